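# name: invasion-stage
# kind: closed-set
# source: https://doi.org/10.1016/j.tree.2011.03.023
# version: unified invasion framework degrees of establishment (replaceable data file)
casual
naturalized
invasive
established
colonizing
introduced
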