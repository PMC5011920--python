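>H1_canonical family=H1 variant=canonical somatic linker histone, human H1.4-type consensus reconstruction
SETAPAAPAAPAPAEKTPVKKKARKSAGAAKRKASGPPVSELITKAVAASKERSGVSLAALKKALAAAGY
DVEKNNSRIKLGLKSLVSKGTLVQTKGTGASGSFKLNKKAASGEAKPKAKKAGAAKAKKPAGAAKKPKKA
TGAATPKKSAKKTPKKAKKPAAAAGAKKAKSPKKAKATKAKKAPKSPAKAKAVKPKAAKPKTAKPKAAKP
KKAAAKKK
>H2A_canonical family=H2A variant=canonical core histone H2A, human type-1 consensus reconstruction
SGRGKQGGKARAKAKTRSSRAGLQFPVGRVHRLLRKGNYAERVGAGAPVYLAAVLEYLTAEILELAGNAA
RDNKKTRIIPRHLQLAIRNDEELNKLLGKVTIAQGGVLPNIQAVLLPKKTESHHKAKGK
>H2AX_variant family=H2A variant=H2A.X H2A.X variant with C-terminal SQEY tetrad, human consensus reconstruction
SGRGKTGGKARAKAKSRSSRAGLQFPVGRVHRLLRKGHYAERVGAGAPVYLAAVLEYLTAEILELAGNAA
RDNKKTRIIPRHLQLAIRNDEELNKLLGGVTIAQGGVLPNIQAVLLPKKTSATVGPKAPSGGKKATQASQ
EY
>H2AZ_variant family=H2A variant=H2A.Z H2A.Z variant, human consensus reconstruction
AGGKAGKDSGKAKTKAVSRSQRAGLQFPVGRIHRHLKSRTTSHGRVGATAAVYSAAILEYLTAEVLELAG
NASKDLKVKRITPRHLQLAIRGDEELDSLIKATIAGGGVIPHIHKSLIGKKGQQKTV
>macroH2A_synthetic family=H2A variant=macroH2A SYNTHETIC stand-in: H2A histone fold plus basic linker plus macro-domain-length filler
SSRGGKKKSTKTSRSAKAGVIFPVGRMLRYIKKGHPKYRIGVGAPVYMAAVLEYLTAEILELAGNAARDN
KKGRVTPRHILLAVANDEELNQLLKGVTIASGGVLPNIHPELLAKKRGSKGKKSPKKAKSTKAGKKTFMY
FNYIWMTGPDLKVLYSARSYIALIDSCPWTPIAKTLKDPYALAFQKYRYFNNSAHRDYKREPMLYYEPSN
QQTMGEESISPCWMAMEDLIIGAPSLECIDRCNASLQWKEDWHDRTEEKKSDDSAEWAKKHILENDGRQP
LLDLLIFPGYLKGLTCQTLPDPFSWYGNMGLYECGLMEDNYKWWGVYRAYSDIFPYSITPEKSDDLAPEL
ADGYIKIGHNPLEIAGEESTNN
>H2B_canonical family=H2B variant=canonical core histone H2B, human type-1 consensus reconstruction
PEPAKSAPAPKKGSKKAVTKAQKKDGKKRKRSRKESYSVYVYKVLKQVHPDTGISSKAMGIMNSFVNDIF
ERIAGEASRLAHYNKRSTITSREIQTAVRLLLPGELAKHAVSEGTKAVTKYTSSK
>H3_canonical family=H3 variant=canonical core histone H3.1, human consensus reconstruction
ARTKQTARKSTGGKAPRKQLATKAARKSAPATGGVKKPHRYRPGTVALREIRRYQKSTELLIRKLPFQRL
VREIAQDFKTDLRFQSSAVMALQEACEAYLVGLFEDTNLCAIHAKRVTIMPKDIQLARRIRGERA
>H33_variant family=H3 variant=H3.3 replacement histone H3.3, human consensus reconstruction
ARTKQTARKSTGGKAPRKQLATKAARKSAPSTGGVKKPHRYRPGTVALREIRRYQKSTELLIRKLPFQRL
VREIAQDFKTDLRFQSAAIGALQEASEAYLVGLFEDTNLCAIHAKRVTIMPKDIQLARRIRGERA
>CENPA_variant family=H3 variant=CENP-A centromeric H3-derived variant with extended N-terminal tail, human consensus reconstruction
MGPRRRSRKPEAPRRRSPSPTPTPGPSRRGPSLGASSHQHSRRRQGWLKEIRKLQKSTHLLIRKLPFSRL
AREICVKFTRGVDFNWQAQALLALQEAAEAYLVGLFEDTNLCAIHAKRVTIMPKDIQLARRIRGLEEGLG
>H4_canonical family=H4 variant=canonical core histone H4, human consensus reconstruction
SGRGKGGKGLGKGGAKRHRKVLRDNIQGITKPAIRRLARRGGVKRISGLIYEETRGVLKVFLENVIRDAV
TYTEHAKRKTVTAMDVVYALKRQGRTLYGFGG
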