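case_id	group	age_years	sex	ab_score	tau_score
DC1001	Young	6	M	-	-
DC1013	Young	4	?	+	-
DC1029	Young	4	F	-	-
DC1033	Young	4	F	-	-
DC1037	Young	6	F	+	-
DC1060	Young	2	F	-	-
DC1062	Young	7	F	+	-
DC1011	Aged	20	M	-	-
DC1012	Aged	25	M	+	+
DC1014	Aged	19	F	+	-
DC1022	Aged	15	F	-	-
DC1023	Aged	16	M	+	-
DC1036	Aged	17	F	+	++
DC1041	Aged	14	M	+	-
DC1043	Aged	15	F	+	-
DC1050	Aged	14	M	-	-
DC1063	Aged	16	F	+	++
DC1005	CDS	18	F	-	++
DC1018	CDS	14	F	-	-
DC1024	CDS	19	M	-	-
DC1030	CDS	16	F	+	++
DC1042	CDS	19	F	+	-
DC1044	CDS	10	F	+	-
DC1049	CDS	19	F	-	-
DC1052	CDS	19	M	-	+++
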