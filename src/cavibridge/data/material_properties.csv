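name,rho_kg_m3,mu_mPa_s,gamma_mN_m,lambda_ms,G_Pa,class
water,998,1.0,72.1,,,newtonian
glycerol_78wt,1212,43.60,65.2,,,newtonian
water_dye_05wt,1000,0.91,47.0,,,newtonian
peo_600k_01wt,996,1.56,63.1,0.31,,viscoelastic
peo_600k_10wt,998,21.70,62.9,1.32,,viscoelastic
peo_1m_10wt,998,44.74,59.2,6.14,,viscoelastic
agarose_015wt,1000,18.96,252.9,,176,gel
agarose_025wt,1000,40.53,620.2,,536,gel
agarose_050wt,1000,256.34,4120.4,,3961,gel
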