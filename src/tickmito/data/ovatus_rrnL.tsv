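id	OM368266	OM368268	OM368269	OM317739	OP244856	OP244857	OP244858
OM368266	0.0000	0.1294	0.1403	0.1844	0.1982	0.1989	0.1972
OM368268	0.1294	0.0000	0.0345	0.1945	0.1988	0.1974	0.1978
OM368269	0.1403	0.0345	0.0000	0.1992	0.1936	0.1911	0.1925
OM317739	0.1844	0.1945	0.1992	0.0000	0.0740	0.0740	0.0731
OP244856	0.1982	0.1988	0.1936	0.0740	0.0000	0.0024	0.0008
OP244857	0.1989	0.1974	0.1911	0.0740	0.0024	0.0000	0.0016
OP244858	0.1972	0.1978	0.1925	0.0731	0.0008	0.0016	0.0000
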