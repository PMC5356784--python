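patient,age_years,gender,tumor_location,surgical_resection,braf_status,fgfr1_duplication,ihc_pfgfr1,fgfr1_exon12,fgfr1_exon14,progression,overall_survival_months,last_followup
DNT18,7,m,temporal,NA,Non-mutated,No,+/-,NA,NA,Yes,164.4,NA
DNT17,5,f,temporal,Complete,V600E,No,Negative,Non-mutated,Non-mutated,No,51.7,FOD
DNT12,12,m,temporal,Complete,V600E,No,Negative,Non-mutated,NA,No,100,FOD
DNT07,9,f,temporal,Complete,Non-mutated,No,Negative,Non-mutated,Non-mutated,Yes,186.8,FOD
DNT04,13,m,temporal,Complete,Non-mutated,No,Negative,NA,NA,No,6.1,NA
DNT19,15,m,frontal,Complete,Non-mutated,No,Negative,NA,NA,No,83.8,FOD
DNT11,13,m,temporal,Complete,V600E,Inconclusive,Negative,Non-mutated,NA,No,67.5,FOD
DNT20,15,f,temporal,Partial,Non-mutated,Yes,Positive,G539R,Non-mutated,Yes,95.6,FOD
DNT14,10,f,occipital,Complete,Non-mutated,Yes,Positive,Non-mutated,NA,No,96,FOD
DNT03,15,m,frontal,Complete,Non-mutated,Yes,NA,Non-mutated,NA,No,36.4,NA
DNT21,3,m,frontal,NA,Non-mutated,Yes,Positive,Non-mutated,Non-mutated,No,54,FOD
DNT10,11,m,temporal,Complete,Non-mutated,Yes,Positive,Non-mutated,Non-mutated,No,97.2,FOD
PTO01,16,m,parietal,Complete,Non-mutated,No,+/-,NA,NA,Yes,135.4,FOD
PTO02,17,f,temporal,Partial,V600E,No,+/-,NA,NA,No,69.1,FOD
PDA01,11,m,temporal,Complete,Non-mutated,No,Negative,NA,NA,Yes,119.9,FOD
PDA02,0,m,temporal,Partial,V600E,No,Negative,Non-mutated,Non-mutated,No,72.9,FOD
PDA03,12,f,temporal,NA,V600E,No,Negative,Non-mutated,Non-mutated,No,60.3,FOD
GG04,11,m,temporal,Complete,Non-mutated,No,+/-,NA,NA,No,109,FOD
GG30,14,m,brainstem + spinal cord,Partial,V600E,No,Negative,NA,NA,Yes,170.9,AWSD
GG11,14,m,frontal,Complete,V600E,No,Negative,Non-mutated,Non-mutated,No,55.1,FOD
GG21,12,f,parietal,Complete,Non-mutated,No,Negative,Non-mutated,Non-mutated,No,32.7,AWSD
GG09,1,f,brainstem,Partial,Non-mutated,No,Negative,Non-mutated,Non-mutated,No,122.2,FOD
GG22,1,m,parietal + occipital,Complete,Non-mutated,No,+/-,NA,NA,No,217.5,NA
GG06,6,m,spinal cord,Complete,V600E,No,Negative,Non-mutated,Non-mutated,No,116.3,FOD
GG14,12,m,temporal,Partial,Non-mutated,No,+/-,L548L,NA,No,57.9,FOD
GG12,13,m,temporal,Complete,Non-mutated,No,+/-,Non-mutated,Non-mutated,Yes,205.6,FOD
GG31,14,f,temporal,Complete,V600E,No,Negative,Non-mutated,L644L,No,104.8,FOD
GG19,6,f,posterior fossa,Complete,Non-mutated,No,+/-,Non-mutated,Non-mutated,No,8.2,NA
GG07,1,f,brainstem,Complete,Non-mutated,No,Negative,Non-mutated,Non-mutated,No,130.4,AWSD
GG18,13,f,third ventricle,Partial,V600E,No,Negative,Non-mutated,Non-mutated,Yes,134.6,AWSD
GG16,12,f,frontal,Complete,Non-mutated,No,Negative,Non-mutated,Non-mutated,No,97.8,FOD
PA14,9,m,cerebellum,Complete,Non-mutated,No,Negative,Non-mutated,Non-mutated,No,64.9,FOD
PA19,3,m,cerebellum,NA,V600E,No,NA,Non-mutated,NA,No,132.5,FOD
PA11,9,m,cerebellum,Complete,V600E,No,Negative,Non-mutated,Non-mutated,No,15.4,FOD
PA01,4,m,cerebellum,Complete,Non-mutated,No,Negative,NA,NA,Yes,190.8,AWSD
PA21,4,m,cerebellum,Partial,Non-mutated,No,Negative,Non-mutated,Non-mutated,Yes,59.3,FOD
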