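palindrome	component	start	end	size	orientation
W.P1	Pre-arm	8778973	8791042	12070	+
W.P1	arm1	8790932	8811002	20071	+
W.P1	Spacer1	8811003	8814588	3586	.
W.P1	arm2	8814589	8834138	19550	-
W.P2	arm3a	8836813	8850772	13960	+
W.P2	arm3b	8850773	8920527	69755	+
W.P2	Spacer2	NA	NA	NA	.
W.P2	arm4b	8920528	8993098	72571	-
W.P2	arm4a	8993099	9013390	20292	-
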