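region,lobe,pathway,models
Pt,subcortical,Striatum,anatomical
Cd,subcortical,Striatum,anatomical
Hc,limbic,Limbic,anatomical;functional
Amy,limbic,Limbic,anatomical;functional
FC,frontal,Neocortex,anatomical
OC,occipital,Neocortex,anatomical
TC,temporal,Neocortex,anatomical
PC,parietal,Neocortex,anatomical
OFC,frontal,Limbic,functional
ACC,cingulate,Limbic;Associative,functional
BA9,frontal,Associative,functional
BA46,frontal,Associative,functional
Precentral,frontal,Sensorimotor,functional
Postcentral,parietal,Sensorimotor,functional
SuperiorParietal,parietal,Sensorimotor,functional
VST,subcortical,striatal-subdivision,functional
AST,subcortical,striatal-subdivision,functional
SMS,subcortical,striatal-subdivision,functional
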