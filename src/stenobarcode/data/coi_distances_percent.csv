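,Cyprus,Volpago,Lovran,Barbarano,Frosinone,Isola Fossara,Frasassi,Randazzo,Iran,Vernante,Valdieri,Giavera
Cyprus,,26.6,27.0,27.4,25.1,26.0,25.3,24.5,23.4,24.4,24.4,22.9
Volpago,22.1,,22.4,20.5,16.6,21.2,21.2,16.6,19.9,18.9,19.5,23.8
Lovran,22.4,19.2,,19.5,23.7,23.0,21.7,23.5,22.6,22.4,23.0,23.0
Barbarano,22.6,17.8,17.0,,18.0,10.4,10.2,20.3,21.3,20.4,21.0,24.0
Frosinone,21.2,14.7,20.1,15.9,,18.5,18.7,6.5,16.1,17.2,17.4,23.5
Isola Fossara,21.6,18.2,19.5,9.5,16.3,,7.6,20.6,22.3,21.3,21.6,23.8
Frasassi,21.2,18.2,18.6,9.5,16.4,7.0,,21.0,20.1,20.2,20.5,23.1
Randazzo,20.7,14.7,20.0,17.6,6.2,17.8,18.1,,16.5,16.8,16.6,22.3
Iran,19.9,17.2,19.3,18.4,14.4,19.0,18.1,14.6,,16.2,16.4,24.7
Vernante,20.6,16.2,19.2,17.8,15.2,18.4,17.6,14.9,14.4,,0.5,21.3
Valdieri,20.6,16.7,19.6,18.2,15.3,18.6,17.8,14.7,14.5,0.5,,21.9
Giavera,19.5,20.1,19.6,20.3,19.9,20.1,19.6,19.0,20.7,18.2,18.7,
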