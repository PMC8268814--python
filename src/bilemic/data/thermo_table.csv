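surfactant,cmc_mM,x_cmc_e6,T_K,n,dG_kJ_mol,dH_kJ_mol,dS_J_mol_K
NaAdC,0.323,5.82,283.15,6.16,25.1,-8.2,-118
NaAdC,0.433,7.81,288.15,6.53,25.2,-6.5,-110
NaAdC,0.296,5.33,293.15,5.88,25.9,-5.4,-107
NaAdC,0.336,6.06,298.15,7.38,27.3,-2.9,-101
NaAdCH2C,0.488,8.79,288.15,8.56,27.2,-6.4,-117
NaAdCH2C,0.473,8.53,293.15,10.5,28.5,-5.3,-115
NaAdCH2C,0.438,7.89,298.15,11.3,28.8,-3.2,-107
NaAdCH2C,0.442,7.96,303.15,10.3,29.2,-1.5,-101
NaAdCH2C,0.343,6.18,313.15,11.1,31.0,1.5,-94
NaAdCH2C,0.378,6.81,318.15,13.2,32.3,2.1,-95
NatButPhC,0.182,3.28,298.15,48.1,34.4,3.1,-105
NatButPhC,0.220,3.95,303.15,39.3,34.4,5.6,-95
NatButPhC,0.201,3.62,308.15,49.7,35.4,8.4,-88
NatButPhC,0.220,3.95,313.15,53.4,35.8,10.9,-80
NatButPhC,0.256,4.61,318.15,33.9,35.5,12.0,-74
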