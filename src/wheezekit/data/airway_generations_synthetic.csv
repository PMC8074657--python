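# Synthetic per-generation airway geometry table (symmetric dichotomy).
# Representative human upper-airway dimensions: diameters follow classical
# morphometric tables, lengths kept within ~4 diameters per branch, wall
# thickness h = 0.1 a and axial stretch l/l0 = 1.25 applied uniformly.
# Columns: generation index (0 = trachea), airway count, stretched branch
# length (m), unstrained radius (m), wall thickness (m), axial stretch l/l0.
generation,count,length_m,radius_m,wall_thickness_m,stretch
0,1,0.1200,0.00900,0.000900,1.25
1,2,0.0476,0.00650,0.000650,1.25
2,4,0.0190,0.00460,0.000460,1.25
3,8,0.0076,0.00320,0.000320,1.25
4,16,0.0127,0.00226,0.000226,1.25
5,32,0.0107,0.00175,0.000175,1.25
6,64,0.0090,0.00140,0.000140,1.25
7,128,0.0076,0.00115,0.000115,1.25
8,256,0.0064,0.00093,0.000093,1.25
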