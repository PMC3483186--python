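taxon	feeding_group	habitat
Drosophila_melanogaster	yeast_mold	terrestrial
Atrichomelina_pubera	shoreline_saprophage	terrestrial
Sciomyza_simplex	shoreline_snail_predator	terrestrial
Pelidnoptera_nigripennis	millipede_parasitoid	terrestrial
Anticheta_melanosoma	snail_egg_predator	terrestrial
Psacadina_zernyi	shoreline_snail_predator	terrestrial
Sepedon_fuscipennis	?	?
Sepedon_armipes	aquatic_snail_predator	aquatic
Sepedon_praemiosa	aquatic_snail_predator	aquatic
Dictya_borealis	aquatic_snail_predator	aquatic
Dictya_expansa	aquatic_snail_predator	aquatic
Dictya_floridensis	aquatic_snail_predator	aquatic
Dictya_gaigei	aquatic_snail_predator	aquatic
Dictya_pictipes	aquatic_snail_predator	aquatic
Dictya_steyskali	aquatic_snail_predator	aquatic
Dictya_stricta	aquatic_snail_predator	aquatic
Dictya_texensis	aquatic_snail_predator	aquatic
Euthycera_arcuata	slug_parasitoid	terrestrial
Poecilographa_decora	?	?
Elgiva_connexa	aquatic_snail_predator	aquatic
Elgiva_solicita	aquatic_snail_predator	aquatic
Hoplodictya_acuticornis	succineid_parasitoid	terrestrial
Pherbecta_limenitis	?	?
Dictyacium_firmum	?	?
Hedria_mixta	submerged_snail_predator	aquatic
Hydromya_dorsalis	shoreline_snail_predator	terrestrial
Ilione_albiseta	submerged_snail_predator	aquatic
Limnia_boscii	succineid_parasitoid	terrestrial
Trypetoptera_canadensis	terrestrial_snail_predator	terrestrial
Limnia_ottawensis	?	?
Trypetoptera_punctulata	terrestrial_snail_predator	terrestrial
Pherbina_coryleti	shoreline_snail_predator	terrestrial
Limnia_sandovalensis	?	?
Renocera_johnsoni	aquatic_snail_predator	aquatic
Renocera_amanda	clam_parasitoid_below	aquatic
Ethiolimnia_geniculata	?	?
Dichetophora_finlandica	?	?
Renocera_pallida	clam_parasitoid_above	terrestrial
Tetanocera_robusta	aquatic_snail_predator	aquatic
Tetanocera_annae	aquatic_snail_predator	aquatic
Tetanocera_silvatica	shoreline_snail_predator	terrestrial
Tetanocera_freyi	?	?
Tetanocera_plumosa	aquatic_snail_predator	both
Tetanocera_hyalipennis	shoreline_snail_predator	terrestrial
Tetanocera_bergi	aquatic_snail_predator	aquatic
Tetanocera_kerteszi	terrestrial_snail_predator	terrestrial
Tetanocera_valida	slug_parasitoid	terrestrial
Tetanocera_clara	slug_parasitoid	terrestrial
Tetanocera_elata	slug_parasitoid	terrestrial
Tetanocera_plebeja	slug_parasitoid	terrestrial
Tetanocera_arrogans	succineid_parasitoid	terrestrial
Tetanocera_melanostigma	succineid_parasitoid	terrestrial
Tetanocera_oxia	succineid_parasitoid	terrestrial
Tetanocera_rotundicornis	succineid_parasitoid	terrestrial
Tetanocera_ferruginea	aquatic_snail_predator	aquatic
Tetanocera_fuscinervis	shoreline_snail_predator	terrestrial
Tetanocera_loewi	aquatic_snail_predator	aquatic
Tetanocera_montana	aquatic_snail_predator	aquatic
Tetanocera_phyllophora	terrestrial_snail_predator	terrestrial
Tetanocera_soror	aquatic_snail_predator	aquatic
Tetanocera_amurensis	?	?
Tetanocera_vicina	aquatic_snail_predator	aquatic
Tetanocera_obtusifibula	aquatic_snail_predator	aquatic
Tetanocera_arnaudi	?	?
Tetanocera_latifibula	aquatic_snail_predator	aquatic
Tetanocera_mesopora	aquatic_snail_predator	aquatic
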