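ligand_id,source_dataset,exp_pic50,classification_prob,predicted_other_pic50
CHEMBL1097353,BACE1,7.85,0.99,6.85
CHEMBL1916166,BACE1,8.57,0.99,7.09
CHEMBL1916158,BACE1,8.59,0.99,6.87
CHEMBL1916168,BACE1,8.00,0.99,7.14
CHEMBL1916170,BACE1,8.85,0.99,6.87
CHEMBL1916169,BACE1,8.82,0.99,6.87
CHEMBL1916167,BACE1,8.52,0.99,6.81
CHEMBL3973939,BACE1,7.80,0.99,7.20
CHEMBL573106,BACE1,9.46,0.99,7.17
CHEMBL3922159,BACE1,7.01,0.99,7.41
CHEMBL1651246,AChE,7.85,0.99,7.06
CHEMBL74359,AChE,6.95,0.99,7.28
CHEMBL74747,AChE,7.09,0.99,7.28
CHEMBL1651127,AChE,7.60,0.99,7.04
CHEMBL76470,AChE,7.44,0.99,7.28
CHEMBL1651126,AChE,7.64,0.99,7.04
CHEMBL1083662,AChE,7.27,0.99,6.94
CHEMBL1651243,AChE,8.54,0.99,7.39
CHEMBL310918,AChE,7.19,0.99,7.32
CHEMBL5082250,AChE,9.24,0.99,7.03
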