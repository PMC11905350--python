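onset_s,offset_s
30.0,35.0
60.0,65.0
90.0,95.0
120.0,125.0
150.0,155.0
180.0,185.0
210.0,215.0
240.0,245.0
270.0,275.0
300.0,305.0
330.0,335.0
360.0,365.0
390.0,395.0
420.0,425.0
450.0,455.0
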