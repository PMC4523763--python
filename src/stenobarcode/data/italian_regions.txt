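Maritime Alps
Berici hills
Venetian Prealps
Istria
Umbro-Marchigian Apennines
Ausoni hills
Sicily
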