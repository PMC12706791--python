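{
 "version": 1,
 "description": "Diagnostic 13C markers per pyranoxanthone subtype. Values flagged in source comments are narrative anchors; the remainder are curated complements chosen for subtype separability.",
 "no_data_subtypes": [
  "B14",
  "B30",
  "C20",
  "C42"
 ],
 "markers": [
  {
   "subtype": "A20",
   "role": "pyran_O_Cq",
   "label": "C-2",
   "expected_ppm": 151.7,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A20",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 120.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A20",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 131.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A20",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 182.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A20",
   "role": "core_CH",
   "label": "C-4",
   "expected_ppm": 88.1,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A23",
   "role": "pyran_O_Cq",
   "label": "C-2",
   "expected_ppm": 156.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A23",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 121.3,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A23",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 132.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A23",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 182.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "A23",
   "role": "core_CH",
   "label": "C-4",
   "expected_ppm": 94.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B13",
   "role": "core_CH",
   "label": "C-2",
   "expected_ppm": 91.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B13",
   "role": "pyran_O_Cq",
   "label": "C-1",
   "expected_ppm": 158.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B13",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 115.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B13",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 126.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B13",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 176.1,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B31",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 115.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B31",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 127.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B31",
   "role": "pyran_O_Cq",
   "label": "C-3",
   "expected_ppm": 157.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B31",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 183.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B31",
   "role": "core_CH",
   "label": "C-4",
   "expected_ppm": 100.6,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B34",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 115.6,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B34",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 127.6,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B34",
   "role": "pyran_O_Cq",
   "label": "C-3",
   "expected_ppm": 151.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B34",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 177.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "B34",
   "role": "core_CH",
   "label": "C-1",
   "expected_ppm": 84.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C21",
   "role": "pyran_O_Cq",
   "label": "C-2",
   "expected_ppm": 153.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C21",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 123.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C21",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 129.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C21",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 184.2,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C21",
   "role": "core_CH",
   "label": "C-4",
   "expected_ppm": 81.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C24",
   "role": "pyran_O_Cq",
   "label": "C-2",
   "expected_ppm": 149.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C24",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 121.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C24",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 129.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C24",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 176.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C24",
   "role": "core_CH",
   "label": "C-1",
   "expected_ppm": 88.1,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C40",
   "role": "pyran_O_Cq",
   "label": "C-4",
   "expected_ppm": 141.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C40",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 121.2,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C40",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 130.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C40",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 176.2,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C40",
   "role": "core_CH",
   "label": "C-1",
   "expected_ppm": 81.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C41",
   "role": "pyran_O_Cq",
   "label": "C-4",
   "expected_ppm": 143.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C41",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 118.9,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C41",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 130.4,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C41",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 182.6,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "C41",
   "role": "core_CH",
   "label": "C-2",
   "expected_ppm": 84.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D31",
   "role": "core_CH",
   "label": "C-2",
   "expected_ppm": 98.0,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D31",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 115.9,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D31",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 127.9,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D31",
   "role": "pyran_O_Cq",
   "label": "C-3",
   "expected_ppm": 159.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D31",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 180.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D32",
   "role": "pyran_O_Cq",
   "label": "C-3",
   "expected_ppm": 146.2,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D32",
   "role": "core_CH",
   "label": "C-1",
   "expected_ppm": 104.5,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D32",
   "role": "pyran_olefinic_1p",
   "label": "C-1'",
   "expected_ppm": 116.8,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D32",
   "role": "pyran_olefinic_2p",
   "label": "C-2'",
   "expected_ppm": 128.9,
   "tolerance_ppm": 1.5
  },
  {
   "subtype": "D32",
   "role": "carbonyl",
   "label": "C-9",
   "expected_ppm": 176.5,
   "tolerance_ppm": 1.5
  }
 ]
}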