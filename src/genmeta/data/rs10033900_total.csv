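study_id,snp,year,country,ethnicity,amd_type,source_of_control,genotyping,case_cc,case_ct,case_tt,ctrl_cc,ctrl_ct,ctrl_tt
Yang 2014,rs10033900,2014,China,Asian,neovascular,HB,MALDI-TOF MS,32,141,127,35,138,126
Seddon 2010,rs10033900,2010,U.S.A.,Caucasian,advanced_AMD,PB,MALDI-TOF MS,120,278,147,87,134,54
Reynolds 2009,rs10033900,2009,U.S.A.,Caucasian,advanced_AMD,PB,MALDI-TOF MS,29,50,23,20,28,7
Cipriani 2012a,rs10033900,2012,U.K.,Caucasian,advanced_AMD,PB,Mixed methods,186,407,211,101,207,102
Cipriani 2012b,rs10033900,2012,U.K.,Caucasian,advanced_AMD,PB,Mixed methods,45,130,47,80,177,77
Wu 2013,rs10033900,2013,China,Asian,AMD,HB,PCR-RFLP,13,68,154,12,58,70
Smailhodzic 2012,rs10033900,2012,The Netherlands,Caucasian,neovascular,HB,Sequencing,48,92,52,29,80,35
Aygun 2019,rs10033900,2019,Turkey,Caucasian,advanced_AMD,HB,Sequencing,26,54,29,24,39,29
Qian 2014,rs10033900,2014,China,Asian,AMD,HB,TaqMan,48,127,113,48,152,184
Kondo 2010,rs10033900,2010,U.S.A.,Caucasian,neovascular,HB,TaqMan,6,59,51,31,85,73
Peter 2011,rs10033900,2011,U.S.A.,Caucasian,AMD,PB,TaqMan,34,68,44,348,623,289
Yu 2011,rs10033900,2011,U.S.A.,Caucasian,advanced_AMD,PB,TaqMan,243,521,308,65,107,44
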