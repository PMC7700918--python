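# Default objective-function template for whole-breast hybrid planning at
# 5000 cGy.  The first round is intentionally weighted toward OAR sparing
# (OAR weights 5x the target weights) so early optimization concentrates on
# target coverage against one competing organ at a time.
structure,kind,dose_cGy,volume_pct,weight,is_oar
PTV_planning,min_dvh,4750,95,20,false
PTV_planning,min_dose,4600,,20,false
PTV_planning,max_dose,5350,,20,false
PTV_planning,uniform_dose,5000,,10,false
Ipsilateral Lung,max_dvh,1900,14,100,true
Heart,max_dvh,2400,9,100,true
Heart,max_mean,350,,100,true
Contralateral Lung,max_dvh,450,14,100,true
Contralateral Breast,max_mean,250,,100,true
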