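# name: iso3166-2-BE
# kind: closed-set
# source: https://www.iso.org/obp/ui/#iso:code:3166:BE
# version: ISO 3166-2:BE (2020), regions + provinces
BE-BRU
BE-VLG
BE-WAL
BE-VAN
BE-VBR
BE-VLI
BE-VOV
BE-VWV
BE-WBR
BE-WHT
BE-WLG
BE-WLX
BE-WNA
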