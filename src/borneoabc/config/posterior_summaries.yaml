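# Reported posterior summaries (median and 95% HPD bounds, linear scale)
# from the original microsatellite ABC analysis of the Sabah elephant data.
# Used only to parameterize the mtDNA zero-diversity experiment, where the
# demographic parameters are drawn "from the posteriors" of that analysis.
# Sizes in effective diploid individuals, times in generations.
AC:
  N_anc: {median: 32681, hpd_low: 10747, hpd_high: 87096}
  N_cur: {median: 480, hpd_low: 257, hpd_high: 969}
  T_shrink: {median: 1207, hpd_low: 1018, hpd_high: 1463}
  N_shrink: {median: 29, hpd_low: 5, hpd_high: 49}
RI:
  N_anc: {median: 1971, hpd_low: 602, hpd_high: 6918}
  N_cur: {median: 448, hpd_low: 245, hpd_high: 977}
  T_shrink: {median: 46, hpd_low: 24, hpd_high: 69}
  N_shrink: {median: 23, hpd_low: 7, hpd_high: 47}
ACS:
  N_anc: {median: 31325, hpd_low: 10000, hpd_high: 89125}
  N_cur: {median: 498, hpd_low: 251, hpd_high: 977}
  T_shrink: {median: 1224, hpd_low: 1020, hpd_high: 1471}
  N_shrink: {median: 28, hpd_low: 9, hpd_high: 49}
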