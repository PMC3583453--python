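synth0	556	594	GT/CA:CA:19:mature	19	+
synth0	1120	1130	TC/AG:AG:5:young_adult	5	+
synth0	1688	1698	TC/AG:CT:5:young_adult	5	+
synth0	2207	2235	TC/AG:AG:14:mature	14	+
synth0	2761	2773	GT/CA:AC:6:young_adult	6	+
synth0	3305	3343	GT/CA:CA:19:mature	19	+
synth0	3884	3896	GT/CA:CA:6:young_adult	6	+
synth0	4426	4448	TC/AG:GA:11:mature	11	+
synth0	4993	5015	TC/AG:AG:11:mature	11	+
synth0	5539	5567	TC/AG:AG:14:mature	14	+
synth0	6100	6112	GT/CA:CA:6:young_adult	6	+
synth0	6630	6652	GC/CG:CG:11:mature	11	+
synth0	7165	7185	GT/CA:CA:10:mature	10	+
synth0	7765	7785	GT/CA:CA:10:mature	10	+
synth0	8325	8345	AT/TA:AT:10:mature	10	+
synth0	8896	8916	AT/TA:TA:10:mature	10	+
synth0	9470	9490	GT/CA:GT:10:mature	10	+
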