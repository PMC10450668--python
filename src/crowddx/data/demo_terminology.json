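[
 {
  "id": "39898005",
  "fsn": "Sleep disorder (disorder)",
  "tag": "disorder",
  "synonyms": ["Sleep disorder", "Disorder of sleep"],
  "parents": []
 },
 {
  "id": "73430006",
  "fsn": "Sleep apnea (disorder)",
  "tag": "disorder",
  "synonyms": ["Sleep apnea", "Sleep apnoea"],
  "parents": ["39898005"]
 },
 {
  "id": "78275009",
  "fsn": "Obstructive sleep apnea syndrome (disorder)",
  "tag": "disorder",
  "synonyms": [
   "Obstructive sleep apnea syndrome",
   "Obstructive sleep apnea",
   "osa",
   "OSA",
   "OSA—obstructive sleep apnea"
  ],
  "parents": ["73430006"]
 },
 {
  "id": "60380001",
  "fsn": "Narcolepsy (disorder)",
  "tag": "disorder",
  "synonyms": ["Narcolepsy"],
  "parents": ["39898005"]
 },
 {
  "id": "193462001",
  "fsn": "Insomnia (disorder)",
  "tag": "disorder",
  "synonyms": ["Insomnia", "Sleeplessness"],
  "parents": ["39898005"]
 }
]
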