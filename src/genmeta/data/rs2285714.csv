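study_id,snp,year,country,ethnicity,amd_type,source_of_control,genotyping,case_cc,case_ct,case_tt,ctrl_cc,ctrl_ct,ctrl_tt
Aygun 2019,rs2285714,2019,Turkey,Caucasian,AMD,HB,Sequencing,42,56,13,32,47,17
Wu 2013,rs2285714,2013,China,Asian,AMD,HB,PCR-RFLP,124,111,4,68,71,1
Yang 2014,rs2285714,2014,China,Asian,AMD,HB,MALDI-TOF MS,188,92,20,167,121,11
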