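,Cyprus,Volpago,Lovran,Barbarano,Frosinone,Isola Fossara,Frasassi,Randazzo,Iran,Vernante,Valdieri,Giavera
Cyprus,,2.3,2.2,2.3,2.1,2.2,2.1,2.1,2.0,2.0,2.0,2.0
Volpago,1.5,,1.9,1.8,1.7,1.8,1.8,1.6,1.9,1.9,2.0,2.0
Lovran,1.5,1.4,,1.8,2.0,2.0,1.9,2.0,1.9,1.8,1.9,1.9
Barbarano,1.5,1.4,1.4,,0.17,1.2,1.2,1.8,1.9,1.8,1.9,2.0
Frosinone,1.5,1.3,1.4,1.4,,1.7,1.6,1.1,1.6,1.7,1.8,2.0
Isola Fossara,1.5,1.3,1.4,1.0,1.3,,1.1,1.9,2.0,1.9,2.0,1.9
Frasassi,1.5,1.3,1.4,1.1,1.3,1.0,,1.8,1.8,1.8,1.8,1.9
Randazzo,1.4,1.3,1.4,1.4,0.9,1.3,1.3,,1.6,1.8,1.8,1.9
Iran,1.5,1.4,1.4,1.4,1.3,1.4,1.4,1.2,,1.6,1.6,2.0
Vernante,1.4,1.4,1.4,1.4,1.4,1.4,1.4,1.4,1.3,,0.3,1.9
Valdieri,1.4,1.4,1.4,1.4,1.4,1.3,1.4,1.4,1.3,0.3,,1.9
Giavera,1.4,1.4,1.4,1.4,1.4,1.3,1.3,1.4,1.4,1.3,1.3,
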