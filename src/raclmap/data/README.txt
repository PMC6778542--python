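Packaged data resources
=======================

synthetic_postmortem_bmax.csv
    SYNTHETIC stand-in for an external receptor-density (Bmax, fmol/mg)
    table, constructed to have the qualitative regional ordering of
    post-mortem raclopride autoradiography (striatum >> limbic > neocortex).
    It exists to exercise the cross-modality comparison machinery and the
    documentation examples; it is not measured data and carries no
    quantitative meaning.

region_vocabulary.csv
    Controlled region vocabulary with lobe and pathway membership.
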