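infant_id,day,cooled,enteral_fed,milk_type,nil_by_mouth,antibiotics,parenteral_nutrition,central_line,breastfed_at_breast
B000001,1,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000001,2,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000001,3,1.0,0.0,none,1.0,1.0,0.0,1.0,0.0
B000001,4,0.0,0.0,none,1.0,0.0,0.0,1.0,0.0
B000001,5,0.0,0.0,none,1.0,0.0,0.0,1.0,0.0
B000001,6,0.0,1.0,maternal,0.0,1.0,0.0,1.0,0.0
B000001,7,0.0,1.0,maternal,0.0,1.0,0.0,1.0,0.0
B000001,8,0.0,1.0,maternal,0.0,1.0,0.0,1.0,0.0
B000001,9,0.0,1.0,maternal,0.0,1.0,0.0,1.0,0.0
B000001,10,0.0,1.0,maternal,0.0,1.0,0.0,0.0,0.0
B000001,11,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000001,12,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000001,13,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000001,14,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000001,15,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000001,16,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000001,17,0.0,1.0,maternal,0.0,0.0,0.0,0.0,
B000001,18,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000002,1,1.0,0.0,none,1.0,1.0,0.0,1.0,0.0
B000002,2,1.0,0.0,none,1.0,1.0,0.0,1.0,0.0
B000002,3,1.0,0.0,none,1.0,0.0,0.0,1.0,0.0
B000002,4,0.0,,,,0.0,0.0,1.0,0.0
B000002,5,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000002,6,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000002,7,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000002,8,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000002,9,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000002,10,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,1,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000003,2,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000003,3,1.0,0.0,none,1.0,0.0,1.0,1.0,0.0
B000003,4,0.0,0.0,none,1.0,0.0,0.0,1.0,0.0
B000003,5,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,6,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,7,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,8,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,9,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,10,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,11,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,12,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,13,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,14,0.0,1.0,maternal,0.0,0.0,0.0,0.0,
B000003,15,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000003,16,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000004,1,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000004,2,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000004,3,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000004,4,0.0,1.0,maternal,0.0,0.0,1.0,1.0,0.0
B000004,5,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000004,6,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000004,7,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000004,8,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000005,1,1.0,0.0,none,1.0,1.0,0.0,1.0,0.0
B000005,2,1.0,0.0,none,1.0,1.0,0.0,1.0,0.0
B000005,3,1.0,1.0,maternal,0.0,0.0,0.0,1.0,
B000005,4,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000005,5,0.0,1.0,maternal,0.0,0.0,0.0,1.0,1.0
B000005,6,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,7,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,8,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,9,0.0,1.0,maternal,0.0,0.0,0.0,0.0,
B000005,10,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,11,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,12,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,13,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,14,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,15,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000005,16,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000006,1,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000006,2,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000006,3,1.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000006,4,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000006,5,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000006,6,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000006,7,0.0,1.0,maternal,0.0,1.0,0.0,0.0,0.0
B000006,8,0.0,1.0,maternal,0.0,1.0,0.0,0.0,0.0
B000006,9,0.0,1.0,maternal,0.0,1.0,0.0,0.0,0.0
B000006,10,0.0,1.0,maternal,0.0,1.0,0.0,0.0,0.0
B000006,11,0.0,1.0,maternal,0.0,1.0,0.0,0.0,0.0
B000006,12,0.0,1.0,maternal,0.0,1.0,0.0,0.0,0.0
B000006,13,0.0,1.0,maternal,0.0,1.0,0.0,0.0,0.0
B000007,1,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000007,2,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000007,3,1.0,0.0,none,1.0,1.0,0.0,1.0,0.0
B000007,4,0.0,0.0,none,1.0,0.0,0.0,0.0,0.0
B000007,5,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000007,6,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000007,7,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000007,8,0.0,1.0,maternal,0.0,0.0,0.0,0.0,1.0
B000008,1,1.0,0.0,none,1.0,0.0,1.0,1.0,0.0
B000008,2,1.0,0.0,none,1.0,0.0,1.0,1.0,0.0
B000008,3,1.0,0.0,none,1.0,0.0,1.0,1.0,0.0
B000008,4,0.0,1.0,maternal,0.0,0.0,1.0,1.0,0.0
B000008,5,0.0,1.0,maternal,0.0,1.0,1.0,1.0,0.0
B000008,6,0.0,1.0,maternal,0.0,1.0,0.0,1.0,0.0
B000008,7,0.0,1.0,maternal,0.0,1.0,0.0,1.0,0.0
B000008,8,0.0,1.0,maternal,0.0,1.0,0.0,1.0,0.0
B000008,9,0.0,1.0,maternal,0.0,1.0,0.0,1.0,
B000008,10,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000008,11,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000009,1,1.0,0.0,none,1.0,1.0,1.0,1.0,0.0
B000009,2,1.0,1.0,maternal,0.0,1.0,1.0,1.0,0.0
B000009,3,1.0,0.0,none,1.0,0.0,0.0,1.0,0.0
B000009,4,0.0,1.0,maternal,0.0,0.0,0.0,1.0,0.0
B000009,5,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000009,6,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000009,7,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000009,8,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000009,9,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000010,1,1.0,0.0,none,1.0,0.0,1.0,1.0,0.0
B000010,2,1.0,1.0,maternal,0.0,0.0,1.0,1.0,0.0
B000010,3,1.0,1.0,maternal,0.0,0.0,1.0,1.0,0.0
B000010,4,0.0,1.0,maternal,0.0,0.0,1.0,1.0,0.0
B000010,5,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000010,6,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
B000010,7,0.0,1.0,maternal,0.0,0.0,0.0,0.0,0.0
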