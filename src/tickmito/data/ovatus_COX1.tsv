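id	OM368266	OM368268	OM368269	OM317739	OP244856	OP244857	OP244858
OM368266	0.0000	0.1549	0.1585	0.1894	0.1922	0.1896	0.1913
OM368268	0.1549	0.0000	0.0457	0.1812	0.1608	0.1600	0.1600
OM368269	0.1585	0.0457	0.0000	0.1729	0.1559	0.1534	0.1550
OM317739	0.1894	0.1812	0.1729	0.0000	0.1098	0.1090	0.1091
OP244856	0.1922	0.1608	0.1559	0.1098	0.0000	0.0046	0.0007
OP244857	0.1896	0.1600	0.1534	0.1090	0.0046	0.0000	0.0039
OP244858	0.1913	0.1600	0.1550	0.1091	0.0007	0.0039	0.0000
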