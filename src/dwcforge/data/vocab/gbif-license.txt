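# name: license
# kind: closed-set
# source: https://www.gbif.org/terms
# version: the three GBIF-supported licenses, both URI schemes
http://creativecommons.org/licenses/by/4.0/
https://creativecommons.org/licenses/by/4.0/
http://creativecommons.org/licenses/by-nc/4.0/
https://creativecommons.org/licenses/by-nc/4.0/
http://creativecommons.org/publicdomain/zero/1.0/
https://creativecommons.org/publicdomain/zero/1.0/
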