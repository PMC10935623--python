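# Score-level outcome counts for the 1424-patient ICU pulmonary-embolism cohort.
# Nonsurvivor counts are derived as total_n - survivor_n; the one printed cell that
# conflicts with its row total (sPESI score 2) is reconciled by totals.
pesi_class:
  levels: ["I", "II", "III", "IV", "V"]
  total_n: [98, 160, 256, 248, 662]
  survivor_n: [98, 158, 253, 244, 581]
spesi:
  levels: ["0", "1", "2", "3", "4", "5"]
  total_n: [177, 403, 438, 255, 121, 30]
  survivor_n: [176, 395, 420, 229, 93, 21]
icu_spesi:
  levels: ["0", "1", "2", "3", "4", "5", "6", ">=7"]
  total_n: [168, 365, 393, 244, 137, 72, 32, 13]
  survivor_n: [167, 360, 389, 223, 121, 51, 20, 3]
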