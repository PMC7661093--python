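# name: wgsrpd-level1
# kind: closed-set
# source: https://www.tdwg.org/standards/wgsrpd/
# version: WGSRPD ed. 2 (2001), level-1 continental codes
1
2
3
4
5
6
7
8
9
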