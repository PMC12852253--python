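ligand_id,dg_ache_kcal_mol,ki_ache_printed,ki_ache_unit,hbonds_ache,dg_bace1_kcal_mol,ki_bace1_printed,ki_bace1_unit,hbonds_bace1
CHEMBL502,-10.45,21.79,nM,PHE295,-10.37,25.02,nM,THR72;GLN73
CHEMBL448008,-9.50,108.37,nM,TYR124;HIS447,-8.32,791.03,nM,GLN73;LYS107;PHE108;GLY230;THR232
CHEMBL1083662,-13.37,159.21,pM,PHE295,-11.19,6.22,nM,THR72
CHEMBL1097353,-12.67,517.76,pM,TYR124;ARG296,-12.19,1.17,nM,THR72;GLN73;GLY230
CHEMBL1651126,-13.22,237.71,pM,SER293;PHE295,-11.03,8.29,nM,THR72;GLN73
CHEMBL1651127,-13.21,206.44,pM,TYR72;PHE295,-11.08,7.50,nM,THR72;PHE108
CHEMBL1651243,-12.64,542.27,pM,GLY121;GLY122;PHE295;HIS447,-12.23,1.08,nM,THR72;ARG128;THR232;ASN233
CHEMBL1651246,-12.95,322.67,pM,SER293;TYR341,-11.39,4.47,nM,THR72;ASP228
CHEMBL1916158,-9.74,72.03,nM,TYR124;TRP286;SER293;PHE295;ARG296,-10.01,46.15,nM,GLY11;GLN73;ASP228;THR231;ARG307
CHEMBL1916166,-13.40,151.56,pM,GLY121;GLY122;ARG296,-10.50,20.09,nM,ASP32;GLN73;ARG128;TYR198;THR232
CHEMBL1916167,-9.72,74.61,nM,GLY121;GLY122;ARG296,-14.51,22.95,pM,GLN73;ASP228;THR231;THR232;ASN233
CHEMBL1916168,-10.04,43.55,nM,SER293;ARG296;TYR341,-11.61,3.07,nM,ASP32;GLN73;ARG128;GLY230
CHEMBL1916169,-10.84,11.27,nM,TYR72;THR75,-11.42,4.24,nM,GLY11;GLN73;ASP228;GLY230;THR232
CHEMBL1916170,-12.28,1.00,nM,TYR72;THR75;TYR124,-10.52,19.57,nM,ASP32;THR72;GLY230;THR232
CHEMBL310918,-11.97,1.69,nM,GLY121;GLY122;SER293;PHE295,-10.68,14.73,nM,SER36;ILE126;TYR198;THR232
CHEMBL3922159,-13.85,70.91,pM,ASP74,-9.77,68.86,nM,GLY11;GLN73;THR232
CHEMBL3973939,-12.21,1.11,nM,ASP74;GLY126,-9.03,241.31,nM,GLY230;THR232
CHEMBL5082250,-15.00,10.06,pM,GLY120;ARG296;TYR341,-13.27,187.09,pM,SER36;ASN37;GLN73
CHEMBL573106,-10.21,32.66,nM,TYR72;THR75;TYR124;PHE295,-8.75,384.04,nM,GLY11;GLY230;THR232;ASN233
CHEMBL74359,-11.61,3.11,nM,PHE295;TYR341,-10.32,27.09,nM,THR72
CHEMBL74747,-12.16,1.22,nM,PHE295,-10.67,15.10,nM,THR72;GLN73
CHEMBL76470,-11.71,2.60,nM,PHE295,-10.02,45.58,nM,THR72;GLN73
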