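# Taxon sets used to configure and check the two packaged analyses.
# Names use the canonical (matrix-file) spellings, with underscores for spaces.
groups:
  outgroup_species:      # polarization outgroups of the full analysis
    - Actinocyclus_verrucosus
    - Bathydoris_hodgsoni
    - Berthella_canariensis
    - Bonisa_nakaza
    - Caldukia_affinis
    - Caldukia_albolineata
    - Caldukia_rubiginosa
    - Calycidoris_guentheri
    - Diaphorodoris_luteocincta
    - Dirona_picta
    - Galeojanolus_ionnae
    - Hero_formosa
    - Heterodoris_antipodes
    - Heterodoris_robusta
    - Janolus_australis
    - Janolus_capensis
    - Janolus_hyalinus
    - Janolus_longidentatus
    - Madrella_sanguinea
    - Marionia_echinomuriceae
    - Pinufius_rebus
    - Tritonia_bollandi
    - Tritonia_hombergi
  doridina:
    - Actinocyclus_verrucosus
    - Bathydoris_hodgsoni
    - Calycidoris_guentheri
    - Diaphorodoris_luteocincta
  tritoniidae:
    - Marionia_echinomuriceae
    - Tritonia_bollandi
    - Tritonia_hombergi
  proctonotidae:
    - Bonisa_nakaza
    - Caldukia_affinis
    - Caldukia_albolineata
    - Caldukia_rubiginosa
    - Galeojanolus_ionnae
    - Janolus_australis
    - Janolus_capensis
    - Janolus_hyalinus
    - Janolus_longidentatus
  armina:
    - Armina_aoteana
    - Armina_bayeri
    - Armina_californica
    - Armina_comta
    - Armina_cordellensis
    - Armina_elongata
    - Armina_gilchristi
    - Armina_joia
    - Armina_juliana
    - Armina_loveni
    - Armina_maculata
    - Armina_magna
    - Armina_mulleri
    - Armina_neapolitana
    - Armina_papillata
    - Armina_paucifoliata
    - Armina_punctulata
    - Armina_variolosa
    - Armina_xandra
  dermatobranchus:
    - Dermatobranchus_albineus
    - Dermatobranchus_albopunctulatus
    - Dermatobranchus_albus
    - Dermatobranchus_arminus
    - Dermatobranchus_caeruleomaculatus
    - Dermatobranchus_caesitius
    - Dermatobranchus_cymatilis
    - Dermatobranchus_dendronephthyphagus
    - Dermatobranchus_diagonalis
    - Dermatobranchus_earlei
    - Dermatobranchus_fasciatus
    - Dermatobranchus_fortunatus
    - Dermatobranchus_funiculus
    - Dermatobranchus_gonatophorus
    - Dermatobranchus_kalyptos
    - Dermatobranchus_kokonas
    - Dermatobranchus_leoni
    - Dermatobranchus_marginlatus
    - Dermatobranchus_microphallus
    - Dermatobranchus_multistriatus
    - Dermatobranchus_nigropunctatus
    - Dermatobranchus_oculus
    - Dermatobranchus_ornatus
    - Dermatobranchus_otome
    - Dermatobranchus_phyllodes
    - Dermatobranchus_piperoides
    - Dermatobranchus_pulcherrimus
    - Dermatobranchus_pustulosus
    - Dermatobranchus_rodmani
    - Dermatobranchus_rubidus
    - Dermatobranchus_semilunus
    - Dermatobranchus_semistriatus
    - Dermatobranchus_striatus
    - Dermatobranchus_tongashanensis
    - Dermatobranchus_tuberculatus
  histiomena:
    - Histiomena_marginata

# Root choices of the two packaged analyses.
roots:
  full_78taxa: Berthella_canariensis
  arminidae_55taxa: Histiomena_marginata

# Spelling variants seen in different parts of the source material, mapped to
# the canonical matrix-file spellings.
aliases:
  Actinocylus_verrucosus: Actinocyclus_verrucosus
  Heterodoris_robustus: Heterodoris_robusta
  Dermatobranchus_tongshanensis: Dermatobranchus_tongashanensis
  Dermatobranchus_gonatophora: Dermatobranchus_gonatophorus
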