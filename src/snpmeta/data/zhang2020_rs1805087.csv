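# Bundled reference dataset: 15 published case-control studies of the
# Methionine synthase (MTR) rs1805087 A/G variant and prostate-cancer risk,
# as assembled in the Zhang et al. (2020, Sci Rep 10:13384) meta-analysis.
# Genotype columns give counts of GG (minor-allele homozygote), GA
# (heterozygote) and AA (major-allele homozygote) per arm.
#
# Transcription notes: counts were cross-checked against two constraints --
# each arm's genotypes must sum to the published per-arm sample size, and the
# published per-arm Hardy-Weinberg chi-square p-value must reproduce.
# marchal2008: case GG resolved to 9 (sum to the published n=181; HWE p=0.391
# reproduces), not the naive reading of 29.
study_id,author,year,ethnicity,source,nos,method,case_gg,case_ga,case_aa,ctrl_gg,ctrl_ga,ctrl_aa
ebrahimi2017,Ebrahimi,2017,Asian,HB,6,PCR-RFLP,13,53,34,6,37,57
qu2016,Qu,2016,Asian,HB,8,RT-PCR,20,316,1481,15,319,1692
lopezcortes2013,Lopez-Cortes,2013,SouthAmerican,PB,8,PCR-RFLP,3,9,92,1,4,105
jackson2013,Jackson,2013,African,HB,7,TaqMan,20,82,97,24,82,99
weiner2012,Weiner,2012,European,PB,6,RT-PCR,15,134,221,16,96,173
cai2010,Cai,2010,Asian,HB,6,PCR-RFLP,5,27,185,3,29,188
collin2010,Collin,2010,European,PB,8,GWAS,1,16,32,10,77,174
murabito2007,Murabito,2007,European,PB,7,GWAS,7,55,110,9,69,153
stevens2009,Stevens,2009,European,PB,7,TaqMan,42,351,701,53,324,728
yeager2007,Yeager,2007,European,PB,7,GWAS,48,376,738,38,340,734
protect2008,ProtecT,2008,European,PB,7,TaqMan,52,515,1033,84,637,1355
eeles2008,Eeles,2008,European,PB,7,GWAS,84,590,1176,71,547,1268
amundadottir2006,Amundadottir,2006,European,PB,7,GWAS,60,466,1093,1044,9160,20575
marchal2008,Marchal,2008,European,HB,7,TaqMan,9,54,118,11,55,138
kimura2000,Kimura,2000,European,HB,9,PCR-RFLP,4,41,87,4,44,102
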