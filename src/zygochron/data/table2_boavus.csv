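record_id,lot_id,specimen_id,left_count,right_count,left_condition,right_condition,centrum_length_mm
59189,YPM VP 2770,YPM VP 59189,6,6,intact,intact,8.8
59190-1,YPM VP 2770,YPM VP 59190,8,8,intact,intact,10.41
59190-2,YPM VP 2770,YPM VP 59190,8,8,intact,intact,10.91
59191-1,YPM VP 2770,YPM VP 59191,9,9,intact,intact,10.67
59191-2,YPM VP 2770,YPM VP 59191,9,9,intact,intact,10.98
59191-3,YPM VP 2770,YPM VP 59191,10,10,intact,intact,9.66
59192,YPM VP 2770,YPM VP 59192,11,11,intact,intact,
59193,YPM VP 2770,YPM VP 59193,13,13,intact,intact,10.58
59194,YPM VP 3752,YPM VP 59194,10,10,intact,intact,10.63
59195,YPM VP 3752,YPM VP 59195,12,12,intact,intact,8.61
59196,YPM VP 3752,YPM VP 59196,14,14,intact,intact,9.76
59197,YPM VP 3752,YPM VP 59197,19,19,intact,intact,
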