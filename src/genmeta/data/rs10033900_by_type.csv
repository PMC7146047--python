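study_id,snp,year,country,ethnicity,amd_type,source_of_control,genotyping,case_cc,case_ct,case_tt,ctrl_cc,ctrl_ct,ctrl_tt
Seddon 2010 GA,rs10033900,2010,U.S.A.,Caucasian,geographic_atrophy,PB,MALDI-TOF MS,26,72,41,87,134,54
Reynolds 2009 GA,rs10033900,2009,U.S.A.,Caucasian,geographic_atrophy,PB,MALDI-TOF MS,19,20,14,20,28,7
Seddon 2010 NV,rs10033900,2010,U.S.A.,Caucasian,neovascular,PB,MALDI-TOF MS,94,206,106,87,134,54
Reynolds 2009 NV,rs10033900,2009,U.S.A.,Caucasian,neovascular,PB,MALDI-TOF MS,10,30,9,20,28,7
Yang 2014 NV,rs10033900,2014,China,Asian,neovascular,HB,MALDI-TOF MS,32,141,127,35,138,126
Aygun 2019 GA,rs10033900,2019,Turkey,Caucasian,geographic_atrophy,HB,Sequencing,12,24,10,24,39,29
Smailhodzic 2012 NV,rs10033900,2012,The Netherlands,Caucasian,neovascular,HB,Sequencing,48,92,52,29,80,35
Aygun 2019 NV,rs10033900,2019,Turkey,Caucasian,neovascular,HB,Sequencing,14,30,19,24,39,29
Yu 2011 GA,rs10033900,2011,U.S.A.,Caucasian,geographic_atrophy,PB,TaqMan,56,121,81,65,107,44
Kondo 2010 NV,rs10033900,2010,U.S.A.,Caucasian,neovascular,HB,TaqMan,6,59,51,31,85,73
Yu 2011 NV,rs10033900,2011,U.S.A.,Caucasian,neovascular,PB,TaqMan,187,400,227,65,107,44
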