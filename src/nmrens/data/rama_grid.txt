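# Ramachandran region grid, 10x10 degree cells.
# rows: psi ascending from [-180,-170); cols: phi ascending from [-180,-170)
# F=most favoured  A=additional allowed  G=generously allowed  D=disallowed
AFFFFFFFFFFFFFAGGDDDDDDDDDDDDDDGGAAA
AAAAAAAAAAAAAAAGGDDDDDDDDDDDDDDGGGGG
AAAAAAAAAAAAAAAGGDDDDDDDDDDDDDDGGGGG
GGGGGGGGGGGGGGGGGDDDDDDDDDDDDDDDDDGG
GGGGGGGGGGGGGGGGGDDDDDDDDDDDDDDDDDGG
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
GGGGGGGGGGGGGGGGGDDDDDDDDDDDDDDDDDGG
GGGGGGGGGGGGGGGGGDDDDDDDDDDDDDDDDDGG
AAAAAAAAAAAAAAAGGDDDDDDDDDDDDDDDDDGG
AAAAAAAAAAAAAAAGGDDDDDDDDDDDDDDDDDGG
AAAAAAAAAAAAAAAGGDDDDDDDDDDDDDDDDDGG
AAAAAAAAAAAAAAAGGDDDDDDDDDDDDDDDDDGG
AAAAFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDGG
AAAAFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDGG
AAAAFFFFFFFFFFAGGDDDDDDDDDDDDDDDDDGG
AAAAFFFFFFFFFFAGGDDGGGGGGGGGGGDDDDGG
AAAAFFFFFFFFFFAGGDDGGGGGGGGGGGDDDDGG
AAAAFFFFFFFFFFAGGDDGGAAAAAAAGGDDDDGG
AAAAFFFFFFFFFFAGGDDGGAAAAAAAGGDDDDGG
AAAAAAAAAAAAAAAGGDDGGAAAAAAAGGDDDDGG
AAAAAAAAAAAAAAAGGDDGGAAFFAAAGGDDDDGG
AAAAAAAAAAAAAAAGGDDGGAAFFAAAGGDDDDGG
AAAAAAAAAAAAAAAGGDDGGAAFFAAAGGDDDDGG
AAAAAAAAAAAAAAAGGDDGGAAFFAAAGGDDDDGG
AAAAAAAAAAAAAAAGGDDGGAAFFAAAGGDDDDGG
AAAAAAAAAAAAAAAGGDDGGAAAAAAAGGDDDDGG
AAAAAAAAAAAAAAAGGDDGGAAAAAAAGGDGGGGG
AAAAAAAAAAAAAAAGGDDGGGGGGGGGGGDGGGGG
AFFFFFFFFFFFFFAGGDDGGGGGGGGGGGDGGAAA
AFFFFFFFFFFFFFAGGDDDDDDDDDDDDDDGGAAA
AFFFFFFFFFFFFFAGGDDDDDDDDDDDDDDGGAAA
AFFFFFFFFFFFFFAGGDDDDDDDDDDDDDDGGAAA
AFFFFFFFFFFFFFAGGDDDDDDDDDDDDDDGGAAA
AFFFFFFFFFFFFFAGGDDDDDDDDDDDDDDGGAAA
AFFFFFFFFFFFFFAGGDDDDDDDDDDDDDDGGAAA
AFFFFFFFFFFFFFAGGDDDDDDDDDDDDDDGGAAA
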