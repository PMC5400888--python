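# Kinship term lexicon (UMLS semantic type famg = family group).
husband	kinship	famg
wife	kinship	famg
mother	kinship	famg
father	kinship	famg
mom	kinship	famg
dad	kinship	famg
sister	kinship	famg
brother	kinship	famg
son	kinship	famg
daughter	kinship	famg
aunt	kinship	famg
uncle	kinship	famg
grandmother	kinship	famg
grandfather	kinship	famg
grandma	kinship	famg
grandpa	kinship	famg
cousin	kinship	famg
niece	kinship	famg
nephew	kinship	famg
father in law	kinship	famg
mother in law	kinship	famg
sister in law	kinship	famg
brother in law	kinship	famg
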