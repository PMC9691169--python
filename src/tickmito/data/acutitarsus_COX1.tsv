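id	OM368264	OL800704	OP244859	OP244860	OP244861
OM368264	0.0000	0.0776	0.0775	0.0775	0.0754
OL800704	0.0776	0.0000	0.0065	0.0065	0.0033
OP244859	0.0775	0.0065	0.0000	0.0000	0.0046
OP244860	0.0775	0.0065	0.0000	0.0000	0.0046
OP244861	0.0754	0.0033	0.0046	0.0046	0.0000
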