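region,value,source
Pt,580.0,postmortem
Cd,520.0,postmortem
Hc,25.0,postmortem
Amy,40.0,postmortem
FC,15.0,postmortem
OC,22.0,postmortem
TC,24.0,postmortem
PC,18.0,postmortem
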