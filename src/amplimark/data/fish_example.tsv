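sample_id	17q22	8q24.3	8p11.2	odx_score
F01	amplified	amplified	amplified	46
F02	not amplified	not amplified	amplified	42
F03	borderline	not amplified	amplified	38
F04	amplified	borderline	borderline	36
F05	borderline	amplified	borderline	33
F06	amplified	amplified	amplified	44
F07	amplified	amplified	borderline	42
F08	borderline	borderline	borderline	34
F09	no signal	not amplified	not amplified	13
F10	no signal	not amplified	not amplified	8
F11	not amplified	not amplified	not amplified	5
F12	borderline	not amplified	not amplified	12
F13	not amplified	no signal	no signal	11
F14	not amplified	not amplified	not amplified	11
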