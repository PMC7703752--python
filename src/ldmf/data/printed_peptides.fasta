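>LD4 paxillin LD4 peptide
SASSATRELDELMASLSD
>LD2 paxillin LD2 peptide
NLSELDRLLLELNAVQ
>IBP2 IGFBP2 candidate peptide
TPTQQELDQVLERISTMR
>RGPA2 RALGAPA2 candidate peptide
GDDVLDKLLENIGHT
>CH037 C8orf37 candidate peptide
AEDLDELLDEVESKFATPD
>ICAL calpastatin (CAST) candidate peptide
DAALDDLIDTLGGP
>FIP1 FIP1L1 candidate peptide
SAGEVERLVSELSGGT
>WHAMM WHAMM candidate peptide
PGSMDEVLASLRHG
>LPP LPP candidate peptide (inverse-orientation motif)
AEIDSLTSILADLESS
>RGPA1 RALGAPA1 candidate peptide
EDVLDELLQYLGVT
>CP071 C16orf71 candidate peptide
EAWDLDDILQSLQGQ
>NCOA2 NCOA2 candidate peptide
SELDNLEEILDDLQNSQ
>E41L5 EPB41L5 candidate peptide
ATDELDALLASLTENLID
>PCP2 PCP2 candidate peptide
PTPEMDSLMDMLASTQ
>NCOA3 NCOA3 candidate peptide
GDLDNLDAILGDLTSSD
>RHGO7 ARHGAP7/DLC1-family candidate peptide
DIFPELDDILYHVKGMQ
>PPP2R3A PPP2R3A candidate peptide
SQEEIDKLLMDLESFSQ
>CREB3 CREB3 candidate peptide
SDWEVDDLLCSLLSPPA
>CCDC158 CCDC158 candidate peptide (inverse-orientation motif)
DPTRDLKQLLQELRSVIN
>Scramble scrambled negative-control peptide
LSDAMETSSLRDALE
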