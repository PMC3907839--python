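compound_id,role,ic50_um,dg_exp_kj_per_mol,molar_mass_g_per_mol,net_charge_e
1,train,18,-31.73,210.30,1
2,train,28,-30.59,224.32,1
3,train,1.9,-37.53,260.36,1
4,train,21,-31.34,266.36,1
5,train,100,-27.31,317.41,1
6,train,0.03,-48.22,389.52,1
7,train,0.05,-46.90,382.46,1
8,train,0.28,-42.56,404.60,1
9,train,0.35,-41.89,417.55,1
10,test,12,-32.78,435.52,0
11,test,0.42,-41.42,394.50,1
12,test,8.4,-33.70,290.38,1
13,test,0.31,-42.20,380.47,1
14,test,0.03,-48.22,339.46,1
15,test,3.80,-35.74,273.38,1
16,test,24,-30.99,268.38,1
17,test,2.10,-37.27,464.59,1
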