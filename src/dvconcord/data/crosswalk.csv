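raw_code,scheme,icd10_code
290.0,ICD9,F03
290.4,ICD9,F01.9
291.0,ICD9,F10.4
291.2,ICD9,F10.7
291.5,ICD9,F10.5
291.8,ICD9,F10.3
292.0,ICD9,F19.3
292.1,ICD9,F19.5
292.9,ICD9,F19.9
295.0,ICD9,F20.6
295.1,ICD9,F20.1
295.2,ICD9,F20.2
295.3,ICD9,F20.0
295.6,ICD9,F20.5
295.7,ICD9,F25.9
295.9,ICD9,F20.9
296.0,ICD9,F30.1
296.2,ICD9,F32.9
296.3,ICD9,F33.9
296.4,ICD9,F31.1
296.5,ICD9,F31.3
296.6,ICD9,F31.6
296.7,ICD9,F31.9
297.1,ICD9,F22.0
298.8,ICD9,F23
298.9,ICD9,F29
299.0,ICD9,F84.0
300.00,ICD9,F41.9
300.01,ICD9,F41.0
300.02,ICD9,F41.1
300.3,ICD9,F42.9
300.4,ICD9,F34.1
301.7,ICD9,F60.2
301.83,ICD9,F60.3
301.9,ICD9,F60.9
303.9,ICD9,F10.2
304.0,ICD9,F11.2
304.4,ICD9,F15.2
304.8,ICD9,F19.2
305.0,ICD9,F10.1
305.6,ICD9,F14.1
305.9,ICD9,F19.1
307.1,ICD9,F50.0
307.51,ICD9,F50.2
308.3,ICD9,F43.0
309.0,ICD9,F43.2
309.81,ICD9,F43.1
311,ICD9,F32.9
312.9,ICD9,F91.9
313.81,ICD9,F91.3
314.00,ICD9,F90.0
314.01,ICD9,F90.9
315.2,ICD9,F81.9
317,ICD9,F70
319,ICD9,F79
331.0,ICD9,G30.9
333.4,ICD9,G10
345.9,ICD9,G40.9
758.0,ICD9,Q90.9
780.1,ICD9,R44.3
780.97,ICD9,R41.0
854.0,ICD9,S06.9
959.9,ICD9,T14.9
E958.9,ICD9,X84
42344001,SNOMED,F10.5
7200002,SNOMED,F10.2
15167005,SNOMED,F10.1
66214007,SNOMED,F19.1
191816009,SNOMED,F19.2
58214004,SNOMED,F20.9
68890003,SNOMED,F25.9
69322001,SNOMED,F29
35489007,SNOMED,F32.9
13746004,SNOMED,F31.9
192080009,SNOMED,F34.1
197480006,SNOMED,F41.9
371631005,SNOMED,F41.0
47505003,SNOMED,F43.1
17226007,SNOMED,F43.2
56882008,SNOMED,F50.0
33449004,SNOMED,F60.9
110359009,SNOMED,F79
408856003,SNOMED,F84.0
406506008,SNOMED,F90.9
91138005,SNOMED,F91.9
52448006,SNOMED,F03
26929004,SNOMED,G30.9
58756001,SNOMED,G10
84757009,SNOMED,G40.9
74732009,SNOMED,F99
248062006,SNOMED,X84
127295002,SNOMED,S06.9
55342001,SNOMED,R44.3
40917007,SNOMED,R41.0
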