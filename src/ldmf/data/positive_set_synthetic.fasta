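>PXN synthetic stand-in carrier (not a real protein)
TDSTTTTGTEETPESGDGTDTPPDTGSGGDLDALLADLEPDSTNGNKESNTGGNSDRPGP
GKQNSNGNSPGRSPNPPSGELDRLLLELNPETPEPGRGPGPTNKTNGRGSSSGEPDQGTT
RNQSNSDQDQGSAPPKSTNSDSEELDELMASLSTQSKGPTENPTNQESSGSSSSRSPNNN
SSNDTNTNGGKPENKSTRGSLDRLLQELEGKRTPSSKPSSNGNSQSGKQSETGQEPSDKP
PQRSPPSPDKPKNTGNTDSG
>LPXN synthetic stand-in carrier (not a real protein)
EEPPGNARNNNTSQGSSPPADDKNNGGELDSLLQELEEKPGPSQGTNGGQKQDSQDNPPP
KTDGSQPASENTGKSTSESDNGQSALDELLDSLKSSPGTPSSGPNTSDDTTAGTSSSGTQ
RTQTPDSDTSDQNGEKQKNTKEQRPPEDQELDALMSELRKQGETTKTSDDNQPNPDGSNK
SENDRNSTKAKGPSEQGKNGRSSNNQSQKTLDSLLADLQPNKNNNQNGSKKNNGDNGKGG
TPNGNPEDPG
>TGFB1I1 synthetic stand-in carrier (not a real protein)
ETEQPGKDDPKQGKGKPTGQRNTNKGPQQPNGGGELDDLMAQLSPPRRPDGDGSPPDKGS
SPGPSDANSSDEKPGSPGPPDGKSRGNSNQLDGLLAELESPGNTNNTSDGKGTGQENPGS
NKEGQTNPSGPSNNNSPPANGPDTNRSAVDELLHSLDNTKSPGTTSQNGTPNDDSNEENG
GNGQGNNQTTASQGQQSSAPDTTKELESLLMRLQRRTDDQGPPTKQGKANEPKDKTSDDG
DPSSS
>PAXB synthetic stand-in carrier (not a real protein)
SPSPQSSDKKSNPNKAKSQTESDPDTSGRNLDSLLSDLETTGPGPGRRDGNDTNGTESPG
PQPPETPDSSGTSPRREDAEDGKPEKGSLDELLNNLGRNPNDSSPKKGPKNGKQSPSKGK
RTPPDKSNAQTDGQSTRQTPNSTPELDKLMDSLSNQTTNETSGSTTRPGSGDGSGTKTTP
PGSSSGSDDSSDQSKKSSDKQTVDDLLSTLERGGNDSEPGTTGESTGSQKKTDKPKQNSG
>DLC1 synthetic stand-in carrier (not a real protein)
ETGKTAGKPPAKPPSQGRNDSKSSRPGRSDGSTNASPGSGDPSQNQEGEENEQPQQKERA
LDDLIDTLGGTDSQNKPSDTGKSTSGKGNQPGPSDTPDQSESPPAQDTDGDTQKEQSQSP
QGQPKGKSSS
>ROXAN synthetic stand-in carrier (not a real protein)
PGRSNNPGPKPGKDNQPENPKGNPPSSGAPEQSGKSTGDDEGNKSLTSILADLETQKDGN
GTEQGATPTSSTDQDPEKPKGGGSSKTNTSPGNPSGDRDNDQSPDQNEQG
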