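[
  {
    "name": "APS (2000)",
    "n_nodes": 8285,
    "f0": 0.11,
    "E": 9071,
    "E00": 126,
    "E01": 1539,
    "E11": 7406,
    "r_printed": 0.05,
    "r_adj_printed": 0.11
  },
  {
    "name": "GitHub",
    "n_nodes": 311755,
    "f0": 0.06,
    "E": 1537570,
    "E00": 7432,
    "E01": 149069,
    "E11": 1381069,
    "r_printed": 0.04,
    "r_adj_printed": 0.15
  },
  {
    "name": "DBLP (2010)",
    "n_nodes": 170984,
    "f0": 0.21,
    "E": 322052,
    "E00": 17468,
    "E01": 91738,
    "E11": 212846,
    "r_printed": 0.1,
    "r_adj_printed": 0.14
  },
  {
    "name": "DBLP (2000)",
    "n_nodes": 54966,
    "f0": 0.18,
    "E": 72369,
    "E00": 3123,
    "E01": 18101,
    "E11": 51145,
    "r_printed": 0.11,
    "r_adj_printed": 0.16
  },
  {
    "name": "DBLP (1990)",
    "n_nodes": 13764,
    "f0": 0.15,
    "E": 12178,
    "E00": 384,
    "E01": 2701,
    "E11": 9093,
    "r_printed": 0.09,
    "r_adj_printed": 0.16
  },
  {
    "name": "DBLP (1980)",
    "n_nodes": 2664,
    "f0": 0.11,
    "E": 1765,
    "E00": 24,
    "E01": 274,
    "E11": 1467,
    "r_printed": 0.06,
    "r_adj_printed": 0.16
  },
  {
    "name": "INFORMS (2010)",
    "n_nodes": 1426,
    "f0": 0.16,
    "E": 1009,
    "E00": 34,
    "E01": 247,
    "E11": 728,
    "r_printed": 0.07,
    "r_adj_printed": 0.12
  },
  {
    "name": "SocioPatterns 4",
    "n_nodes": 180,
    "f0": 0.27,
    "E": 2220,
    "E00": 182,
    "E01": 762,
    "E11": 1276,
    "r_printed": 0.09,
    "r_adj_printed": 0.12
  },
  {
    "name": "SocioPatterns 5",
    "n_nodes": 327,
    "f0": 0.44,
    "E": 5818,
    "E00": 1471,
    "E01": 2348,
    "E11": 1999,
    "r_printed": 0.19,
    "r_adj_printed": 0.19
  }
]
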