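# Whole-breast protocol constraint tables (EviQ, RTOG 1005, London Cancer),
# encoded as printed in the guidelines summary used for plan scoring.
# level: dose in cGy for V-metrics, volume % for d-metrics; alt_level is the
# parenthesized alternate level applied under the 4240 cGy/16 regime.
# limit: % for V-metrics, cGy for dose metrics unless limit_kind=pct_of_rx.
# Notes kept as printed even where the pairing is uneven: the RTOG heart
# ideal row is V20 (V16) < 5% while its acceptable counterpart is
# V25 (V20) < 5%.  The bare "Contralateral Breast < 3.1 Gy" bound is
# encoded as a mean-dose limit (the near-maximum is bounded separately
# by the d5 row).
protocol,tier,pair,structure,metric,level,alt_level,limit,limit_kind,cmp
EviQ,target,ptv_d95,PTV,d,95,,95,pct_of_rx,gt
EviQ,ideal,il_v20,Ipsilateral Lung,V,2000,1600,15,pct,lt
EviQ,ideal,heart_v25,Heart,V,2500,2000,10,pct,lt
EviQ,ideal,heart_mean,Heart,mean,,,400,cGy,lt
RTOG1005,target,ptv_d95,PTV,d,95,,95,pct_of_rx,gt
RTOG1005,target,plan_max,Body,max,,,110,pct_of_rx,lt
RTOG1005,ideal,il_v20,Ipsilateral Lung,V,2000,1600,15,pct,lt
RTOG1005,acceptable,il_v20,Ipsilateral Lung,V,2000,1600,20,pct,lt
RTOG1005,ideal,il_v10,Ipsilateral Lung,V,1000,800,35,pct,lt
RTOG1005,acceptable,il_v10,Ipsilateral Lung,V,1000,800,40,pct,lt
RTOG1005,ideal,il_v5,Ipsilateral Lung,V,500,400,50,pct,lt
RTOG1005,acceptable,il_v5,Ipsilateral Lung,V,500,400,55,pct,lt
RTOG1005,ideal,cl_v5,Contralateral Lung,V,500,,10,pct,lt
RTOG1005,acceptable,cl_v5,Contralateral Lung,V,500,,15,pct,lt
RTOG1005,ideal,cb_mean,Contralateral Breast,mean,,,310,cGy,lt
RTOG1005,acceptable,cb_mean,Contralateral Breast,mean,,,500,cGy,lt
RTOG1005,ideal,cb_d5,Contralateral Breast,d,5,,190,cGy,lt
RTOG1005,acceptable,cb_d5,Contralateral Breast,d,5,,310,cGy,lt
RTOG1005,ideal,heart_v10,Heart,V,1000,800,30,pct,lt
RTOG1005,acceptable,heart_v10,Heart,V,1000,800,35,pct,lt
RTOG1005,ideal,heart_v20,Heart,V,2000,1600,5,pct,lt
RTOG1005,acceptable,heart_v20,Heart,V,2500,2000,5,pct,lt
RTOG1005,ideal,heart_mean,Heart,mean,,,400,cGy,lt
RTOG1005,acceptable,heart_mean,Heart,mean,,,500,cGy,lt
LondonCancer,target,ptv_d95,PTV,d,95,,95,pct_of_rx,gt
LondonCancer,target,plan_max,Body,max,,,110,pct_of_rx,lt
LondonCancer,ideal,il_v22,Ipsilateral Lung,V,2200,1800,15,pct,lt
LondonCancer,ideal,heart_v15,Heart,V,1500,1300,10,pct,lt
LondonCancer,ideal,cl_v2.5,Contralateral Lung,V,250,,15,pct,lt
LondonCancer,ideal,cl_mean,Contralateral Lung,mean,,,200,cGy,lt
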