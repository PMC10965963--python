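{
 "fragments": [
  {"id": "Ala_M57", "parts": [["PYR", [1, 2, 3]]], "instrument": "GC-MS"},
  {"id": "Ala_M159", "parts": [["PYR", [2, 3]]], "instrument": "GC-MS"},
  {"id": "Gly_M57", "parts": [["PEP", [1, 2]]], "instrument": "GC-MS"},
  {"id": "Ser_M57", "parts": [["PEP", [1, 2, 3]]], "instrument": "GC-MS"},
  {"id": "Val_M57", "parts": [["PYR", [1, 2, 3]], ["PYR", [2, 3]]], "instrument": "GC-MS"},
  {"id": "Thr_M57", "parts": [["OAA", [1, 2, 3, 4]]], "instrument": "GC-MS"},
  {"id": "Asp_M57", "parts": [["OAA", [1, 2, 3, 4]]], "instrument": "GC-MS"},
  {"id": "Asp_M159", "parts": [["OAA", [2, 3, 4]]], "instrument": "GC-MS"},
  {"id": "Glu_M57", "parts": [["AKG", [1, 2, 3, 4, 5]]], "instrument": "GC-MS"},
  {"id": "Glu_M159", "parts": [["AKG", [2, 3, 4, 5]]], "instrument": "GC-MS"},
  {"id": "X5P", "parts": [["X5P", [1, 2, 3, 4, 5]]], "instrument": "IC-MS"},
  {"id": "R5P", "parts": [["R5P", [1, 2, 3, 4, 5]]], "instrument": "IC-MS"},
  {"id": "S7P", "parts": [["S7P", [1, 2, 3, 4, 5, 6, 7]]], "instrument": "IC-MS"},
  {"id": "F6P", "parts": [["F6P", [1, 2, 3, 4, 5, 6]]], "instrument": "IC-MS"},
  {"id": "G6P", "parts": [["G6P", [1, 2, 3, 4, 5, 6]]], "instrument": "IC-MS"},
  {"id": "6PG", "parts": [["6PG", [1, 2, 3, 4, 5, 6]]], "instrument": "IC-MS"}
 ]
}
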