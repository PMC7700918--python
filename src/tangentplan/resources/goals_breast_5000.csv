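# Default whole-breast clinical goals for the 5000 cGy / 25 fraction regime,
# mirroring the guideline targets the planner is scored against.
structure,kind,dose_cGy,volume_pct,strict
PTV_planning,min_dvh_dose,4750,95,true
PTV_planning,max_dose,5500,,true
Ipsilateral Lung,max_dvh_volume,2000,15,true
Heart,max_dvh_volume,2500,10,true
Heart,max_mean,400,,true
Contralateral Lung,max_dvh_volume,500,15,true
Contralateral Breast,max_mean,310,,true
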