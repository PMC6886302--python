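# Six synthetic demo genes spanning 2-100 kb and 2-4 genomic loci.
# Probe positions are transcript coordinates of each probe's 3'-most nt.
genes:
- name: GENA
  length_nt: 2000
  n_loci: 2
  exon_probe_positions_nt: [78, 232, 354, 492, 600, 717, 804, 982, 1087, 1260, 1317, 1475, 1626, 1681,
    1824, 1946]
  intron_probe_positions_nt: [71, 225, 356, 518, 582, 748, 892, 1005]
- name: GENB
  length_nt: 6000
  n_loci: 3
  exon_probe_positions_nt: [354, 723, 786, 1066, 1335, 1504, 1789, 1906, 2303, 2505, 2625, 2989, 3256,
    3411, 3652, 3969, 4103, 4511, 4761, 4860, 5046, 5443, 5591, 5832]
  intron_probe_positions_nt: [252, 664, 1006, 1564, 1772, 2202, 2588, 3083]
- name: GENC
  length_nt: 10000
  n_loci: 4
  exon_probe_positions_nt: [639, 915, 1201, 1570, 1728, 1879, 2368, 2612, 2862, 3229, 3549, 3798, 4162,
    4395, 4788, 4931, 5297, 5559, 5948, 6174, 6431, 6755, 7027, 7580, 7691, 7889, 8109, 8413, 8843, 9169,
    9439, 9545]
  intron_probe_positions_nt: [409, 907, 1461, 1939, 2483, 2920, 3495, 4042, 4442, 5069]
- name: GEND
  length_nt: 20000
  n_loci: 2
  exon_probe_positions_nt: [1068, 1433, 2379, 2406, 2746, 3452, 3740, 4329, 5070, 5333, 5967, 6279, 6599,
    7200, 7978, 8078, 8517, 8816, 9696, 10027, 10247, 11086, 11240, 12085, 12447, 12940, 13082, 14070,
    14273, 14879, 14879, 15445, 16659, 16753, 17352, 17647, 17893, 18690, 19014, 19533]
  intron_probe_positions_nt: [542, 1691, 2565, 3015, 4079, 4566, 5279, 6127, 7038, 7545, 8690, 9184, 10032]
- name: GENE
  length_nt: 45000
  n_loci: 3
  exon_probe_positions_nt: [2738, 3524, 4208, 5428, 6392, 6977, 7942, 8183, 9174, 10606, 11462, 12327,
    12890, 14098, 14328, 16018, 16874, 17646, 18175, 18778, 19308, 20727, 21866, 22376, 23404, 24419,
    25426, 26535, 27140, 27409, 28725, 29242, 29582, 31265, 32254, 33258, 34204, 35545, 36035, 36482,
    37779, 38734, 38942, 40445, 41761, 41848, 43020, 43435]
  intron_probe_positions_nt: [1500, 2899, 4288, 6163, 7764, 8662, 10089, 11557, 12983, 13927, 15290, 16617,
    18584, 20060, 20935, 22629]
- name: GENF
  length_nt: 100000
  n_loci: 4
  exon_probe_positions_nt: [6488, 9230, 10074, 11151, 14560, 14907, 18873, 19292, 21317, 24738, 25443,
    26734, 29964, 30744, 31875, 34853, 35874, 37378, 40732, 41184, 43103, 46114, 49873, 50351, 52740,
    54459, 55685, 59213, 59802, 61790, 62699, 65301, 67976, 69138, 72031, 74102, 76996, 77716, 80688,
    81173, 82142, 87344, 87811, 89137, 91004, 93204, 96491, 96499]
  intron_probe_positions_nt: [2902, 6569, 11410, 14448, 15804, 18309, 22861, 25398, 29176, 31511, 33981,
    38148, 40072, 44212, 48038, 49233]
design:
  timepoints_h: [0.0, 3.0, 6.0, 9.0]
  treatment: IR_pulsatile
  n_cells_per_timepoint: 200
  seed: 11
telegraph: {k_on_basal: 0.5, k_off: 1.5, init_rate: 160.0, deg_rate: 0.5, export_rate: 3.0, archetype: pulsatile}
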