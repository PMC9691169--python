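id	OM368264	OL800704	OP244859	OP244860	OP244861
OM368264	0.0000	0.0502	0.0491	0.0491	0.0500
OL800704	0.0502	0.0000	0.0024	0.0024	0.0016
OP244859	0.0491	0.0024	0.0000	0.0000	0.0024
OP244860	0.0491	0.0024	0.0000	0.0000	0.0024
OP244861	0.0500	0.0016	0.0024	0.0024	0.0000
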