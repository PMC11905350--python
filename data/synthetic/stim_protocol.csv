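onset_s,offset_s,freq_hz,pulse_width_ms,repeat_idx
6.0,16.0,20.0,5.0,1
22.0,32.0,40.0,5.0,1
38.0,48.0,10.0,5.0,1
54.0,64.0,20.0,5.0,2
70.0,80.0,10.0,5.0,2
86.0,96.0,5.0,5.0,1
102.0,112.0,5.0,5.0,2
118.0,128.0,40.0,5.0,2
134.0,144.0,5.0,5.0,3
150.0,160.0,40.0,5.0,3
166.0,176.0,20.0,5.0,3
182.0,192.0,10.0,5.0,3
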