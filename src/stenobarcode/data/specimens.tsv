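label	region	group
Valdieri	Maritime Alps	ingroup
Vernante	Maritime Alps	ingroup
Barbarano	Berici hills	ingroup
Volpago	Venetian Prealps	ingroup
Giavera	Venetian Prealps	ingroup
Lovran	Istria	ingroup
Isola Fossara	Umbro-Marchigian Apennines	ingroup
Frasassi	Umbro-Marchigian Apennines	ingroup
Frosinone	Ausoni hills	ingroup
Randazzo	Sicily	ingroup
Cyprus	Cyprus	ingroup
Iran	Alborz Mountains	ingroup
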