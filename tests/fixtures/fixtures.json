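{
 "patristic": {
  "Sp0001|Sp0002": 1.4935555653276646,
  "Sp0001|Sp0026": 8.191161451044477,
  "Sp0011|Sp0041": 7.687474402010898
 },
 "pd_set1_root": 8.761591869977225,
 "pd_set1_noroot": 6.488707759955499,
 "pd_all": 66.46460608913539,
 "set1": [
  "Sp0001",
  "Sp0002",
  "Sp0003",
  "Sp0004",
  "Sp0005",
  "Sp0006",
  "Sp0007"
 ],
 "set2": [
  "Sp0021",
  "Sp0022",
  "Sp0023",
  "Sp0024",
  "Sp0025",
  "Sp0026"
 ],
 "mntd_set1_set2": 8.186979839028368
}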