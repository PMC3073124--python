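Berthella_canariensis  000-000200021011000-----00011101----2010000
Actinocyclus_verrucosus  010-0100-0000000000----111000000----2011000
Bathydoris_hodgsoni  010-0100-10000000010-110000111001---0--0000
Calycidoris_guentheri  010-0100-0000000010-----0001111-----2010000
Diaphorodoris_luteocincta  010-0100-0000010010-----1001--1-----2010000
Marionia_echinomuriceae  1-1-00121002101100102110010111001---21?0000
Tritonia_bollandi  1-1-001210021000001101100?0???0000??2111000
Tritonia_hombergi  1-1-001210021000001111100?0???00?0??2?????0
Dirona_picta  1-1-0012000000000110-2101001--001---2000010
Hero_formosa  1-1-0011-0020??0011102101?0???0002????????0
Heterodoris_antipodes  1-100102000010000110-2000?0???001---2100000
Heterodoris_robusta  1-000102000010000111??00??0???001---2010000
Madrella_sanguinea  1-0-01120002100101111210110---001---???1000
Pinufius_rebus  1-0-00120002000001110210------00020?0001000
Bonisa_nakaza  1-0-0011-00000100111020010000-001---1011010
Caldukia_affinis  1-0-0011-00000000110-110000000000---?111010
Caldukia_albolineata  1-0-0011-0000000011101001000000002--?101000
Caldukia_rubiginosa  1-0-0011-0000000011101001000000002--?101010
Galeojanolus_ionnae  1-0-0011-1000010011101001000000002--1000100
Janolus_australis  1-0-0100-00000100110-200000111001---10?01?0
Janolus_capensis  1-0-0011-00000000110-000000111001---1010100
Janolus_hyalinus  1-0-0011-00000100110-000100111001---1000100
Janolus_longidentatus  1-0-0011-0000010011110000001110002211001100
Armina_aoteana  1-10100200111001101101101000000000000000000
Armina_bayeri  1-00100200111011101100101001110000000?????0
Armina_californica  1-00100200111001101101100000010000000010010
Armina_comta  1-10100201?11011101112101001110000000001000
Armina_cordellensis  1-100102?0?11001101112101000110000000001000
Armina_elongata  1-10100210111001101112101000000001000001000
Armina_gilchristi  1-10100200011001101101101?0???0001?00?????0
Armina_joia  1-10100200111011101111101000000000000?????0
Armina_juliana  1-10100200111001101112101000000000000111010
Armina_loveni  1-10100200111001101101101000000001000010000
Armina_maculata  1-10010200011001101101101001110000000010000
Armina_magna  1-10100200011001111101101000010000000000000
Armina_mulleri  1-10100200111011101101101000010001000110010
Armina_neapolitana  1-10100200111001101112101000000000000010000
Armina_papillata  1-10100210111001101112101000000000000001000
Armina_paucifoliata  1-10100200011001101101101000010000000010000
Armina_punctulata  1-10010200111001101112101000000000000000000
Armina_variolosa  1-10010210111101101111101000110000000001000
Armina_xandra  1-00010200111011101112101100110000000?????0
Dermatobranchus_albopunctulatus  1-1110020001100000111200100011001---0??????
Dermatobranchus_albus  1-21100200011000011112101211110000100001000
Dermatobranchus_fortunatus  1-21010200011000021111101210000002120011000
Dermatobranchus_gonatophorus  1-1110020001100000111110100000001---0001000
Dermatobranchus_marginlatus  1-1110020001100000111200100001000000???????
Dermatobranchus_multistriatus  1-1110020001100000111201100011001---???????
Dermatobranchus_nigropunctatus  1-1110020001100000111201100111001---0??????
Dermatobranchus_ornatus  1-1101020001100000111111100111001---0001001
Dermatobranchus_otome  1-21100200011000011112101211110000100011000
Dermatobranchus_pulcherrimus  1-1110020001110000111200100000000000000000?
Dermatobranchus_pustulosus  1-11100200011000001102001000010001100011000
Dermatobranchus_rubidus  1-1110020001110000111200100000000000000100?
Dermatobranchus_semistriatus  1-11100200011000001112101100110002100??????
Dermatobranchus_striatus  1-2110020001100001111210121111000010001100?
Dermatobranchus_tongashanensis  1-1110020001100000111201100011001---???????
Dermatobranchus_albineus  1-11100200011000021111101210110000120001001
Dermatobranchus_arminus  1-11100200011000101111101000010001000001000
Dermatobranchus_caeruleomaculatus  1-1110020001100000111201&00111001---0001000
Dermatobranchus_caesitius  1-11100200011000011112101210000000100001000
Dermatobranchus_cymatilis  1-21100200011000001102001001110001110011000
Dermatobranchus_dendronephthyphagus  1-1110020001100000102201000111001---0011001
Dermatobranchus_diagonalis  1-21100200011000011112101211110000200001000
Dermatobranchus_earlei  1-21100200011000021111101210010002100001000
Dermatobranchus_fasciatus  1-1110020001100000111&101000000000100011000
Dermatobranchus_funiculus  1-21100200011000021112101210010001000001000
Dermatobranchus_kalyptos  1-11010200011000001111101000010000100000000
Dermatobranchus_kokonas  1-21000200011000021112101210010002120001000
Dermatobranchus_leoni  1-1110020001100000111201100011001---0011010
Dermatobranchus_microphallus  1-21100200011000021111101210010002200001000
Dermatobranchus_oculus  1-21100200011000011112101211100000100001000
Dermatobranchus_phyllodes  1-11100200011000001112000001110001000001010
Dermatobranchus_piperoides  1-21000200011000021111101210110001120001010
Dermatobranchus_semilunus  1-21100200011000001112001001110001100001001
Dermatobranchus_rodmani  1-21000200011000021111101210010000120001000
Dermatobranchus_tuberculatus  1-21010200011000011112101100010000000001001
Histiomena_marginata  1-0010021001100110111100000111001---00?0000
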