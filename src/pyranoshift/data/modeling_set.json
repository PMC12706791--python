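{
 "version": 1,
 "description": "Modeling-set catalog of 76 pyranoxanthones (catalog id encodes the subtype code; dual codes mark two pyran rings). Entries with curation='placeholder' hold curated subtype/sequence slots whose trivial names are not recorded here.",
 "compounds": [
  {
   "id": "A20-2",
   "name": "toxyloxanthone E",
   "curation": "named"
  },
  {
   "id": "A20-3-B31-17",
   "name": "thwaitesixanthone",
   "curation": "named"
  },
  {
   "id": "A20-5-D31-7",
   "name": "cudraxanthone A",
   "curation": "named"
  },
  {
   "id": "A23-3",
   "name": "cudraxanthone B",
   "curation": "named"
  },
  {
   "id": "A23-6",
   "name": "garcinone B",
   "curation": "named"
  },
  {
   "id": "A23-8",
   "name": "allanxanthone B",
   "curation": "named"
  },
  {
   "id": "A23-14-B31-20",
   "name": "calophinone",
   "curation": "named"
  },
  {
   "id": "A23-15",
   "name": "calotetrapterin D",
   "curation": "named"
  },
  {
   "id": "A23-16",
   "name": "calotetrapterin E",
   "curation": "named"
  },
  {
   "id": "A23-17",
   "name": "calotetrapterin A",
   "curation": "named"
  },
  {
   "id": "B13-2",
   "name": "garciosone E",
   "curation": "named"
  },
  {
   "id": "B31-3",
   "name": "6-deoxyjacareubin",
   "curation": "named"
  },
  {
   "id": "B31-9",
   "name": "inoxanthone",
   "curation": "named"
  },
  {
   "id": "B31-10",
   "name": "macluraxanthone",
   "curation": "named"
  },
  {
   "id": "B31-12",
   "name": "calabaxanthone",
   "curation": "named"
  },
  {
   "id": "B31-13",
   "name": "3-isomangostin",
   "curation": "named"
  },
  {
   "id": "B31-15-B34-6",
   "name": "pyranojacareubin",
   "curation": "named"
  },
  {
   "id": "B31-19-D32-5",
   "name": "mangostenone A",
   "curation": "named"
  },
  {
   "id": "B34-2",
   "name": null,
   "curation": "named"
  },
  {
   "id": "B34-5",
   "name": "pedunxanthone C",
   "curation": "named"
  },
  {
   "id": "B34-7",
   "name": "demethylpedunxanthone C",
   "curation": "named"
  },
  {
   "id": "D31-12",
   "name": "cudratricusxanthone H",
   "curation": "named"
  },
  {
   "id": "D31-16",
   "name": "demethylsterigmatocystin",
   "curation": "named"
  },
  {
   "id": "D31-17",
   "name": "morusignin H",
   "curation": "named"
  },
  {
   "id": "D31-18",
   "name": "pruniflorone N",
   "curation": "named"
  },
  {
   "id": "D32-1",
   "name": "nigrolineaxanthone H",
   "curation": "named"
  },
  {
   "id": "A20-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A20-4",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A23-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A23-2",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A23-4",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A23-5",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A23-9",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A23-11",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A23-12",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "A23-13",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B13-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-2",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-4",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-6",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-7",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-8",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-11",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-14",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-16",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B31-18",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B34-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B34-3",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B34-4",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "B34-8",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "C21-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "C21-2",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "C24-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "C40-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "C40-2",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "C41-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "C41-2",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-1",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-2",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-3",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-4",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-5",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-6",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-8",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-9",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-10",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-11",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-13",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D31-15",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D32-2",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D32-3",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D32-4",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D32-6",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D32-7",
   "name": null,
   "curation": "placeholder"
  },
  {
   "id": "D32-8",
   "name": null,
   "curation": "placeholder"
  }
 ]
}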