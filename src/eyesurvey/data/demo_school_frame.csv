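# Synthetic demonstration school frame (40 schools, lognormal-like enrollments).
# Columns yg_1..yg_6 are year-group roster counts and sum to enrollment.
school_id,name,enrollment,yg_1,yg_2,yg_3,yg_4,yg_5,yg_6
SCH001,Demo School 1,2893,532,423,487,491,444,516
SCH002,Demo School 2,182,25,27,40,26,32,32
SCH003,Demo School 3,1170,161,220,229,172,213,175
SCH004,Demo School 4,196,31,34,32,35,30,34
SCH005,Demo School 5,1070,177,170,148,207,219,149
SCH006,Demo School 6,1554,212,302,271,254,270,245
SCH007,Demo School 7,632,90,114,107,89,93,139
SCH008,Demo School 8,249,32,37,47,49,51,33
SCH009,Demo School 9,448,82,69,65,86,80,66
SCH010,Demo School 10,44,8,8,7,7,7,7
SCH011,Demo School 11,175,32,23,38,30,25,27
SCH012,Demo School 12,353,65,62,51,64,64,47
SCH013,Demo School 13,2015,269,315,409,300,365,357
SCH014,Demo School 14,443,68,63,80,71,93,68
SCH015,Demo School 15,347,49,70,57,67,48,56
SCH016,Demo School 16,95,16,17,15,13,18,16
SCH017,Demo School 17,317,49,55,49,60,51,53
SCH018,Demo School 18,330,58,65,43,50,53,61
SCH019,Demo School 19,89,14,16,14,17,15,13
SCH020,Demo School 20,503,85,93,87,86,63,89
SCH021,Demo School 21,252,48,51,36,34,51,32
SCH022,Demo School 22,600,74,96,107,112,107,104
SCH023,Demo School 23,635,97,100,116,121,115,86
SCH024,Demo School 24,505,101,72,104,74,72,82
SCH025,Demo School 25,168,23,30,27,27,33,28
SCH026,Demo School 26,587,79,123,114,96,81,94
SCH027,Demo School 27,1312,238,187,186,243,255,203
SCH028,Demo School 28,273,44,43,46,47,41,52
SCH029,Demo School 29,221,31,36,38,49,33,34
SCH030,Demo School 30,976,196,130,137,182,186,145
SCH031,Demo School 31,396,68,67,73,78,62,48
SCH032,Demo School 32,196,27,34,36,36,29,34
SCH033,Demo School 33,104,16,15,16,19,21,17
SCH034,Demo School 34,164,33,27,20,23,33,28
SCH035,Demo School 35,244,27,35,44,47,43,48
SCH036,Demo School 36,173,27,34,33,35,23,21
SCH037,Demo School 37,637,98,107,103,102,139,88
SCH038,Demo School 38,2011,340,302,351,273,359,386
SCH039,Demo School 39,941,195,128,137,205,138,138
SCH040,Demo School 40,128,16,20,26,25,24,17
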