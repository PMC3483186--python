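(Drosophila_melanogaster:1,((Atrichomelina_pubera:1,Sciomyza_simplex:1):1,(Pelidnoptera_nigripennis:1,(Anticheta_melanosoma:1,(Psacadina_zernyi:1,((Sepedon_fuscipennis:1,(Sepedon_armipes:1,Sepedon_praemiosa:1):1):1,((Dictya_borealis:1,(Dictya_expansa:1,(Dictya_floridensis:1,(Dictya_gaigei:1,(Dictya_pictipes:1,(Dictya_steyskali:1,(Dictya_stricta:1,Dictya_texensis:1):1):1):1):1):1):1):1,((Euthycera_arcuata:1,Poecilographa_decora:1):1,((Elgiva_connexa:1,Elgiva_solicita:1):1,((Hoplodictya_acuticornis:1,(Pherbecta_limenitis:1,Dictyacium_firmum:1):1):1,(Hedria_mixta:1,(Hydromya_dorsalis:1,(Ilione_albiseta:1,((Limnia_boscii:1,((Trypetoptera_canadensis:1,(Limnia_ottawensis:1,Trypetoptera_punctulata:1):1):1,(Pherbina_coryleti:1,Limnia_sandovalensis:1):1):1):1,(((Renocera_johnsoni:1,(Renocera_amanda:1,Ethiolimnia_geniculata:1):1):1,(Dichetophora_finlandica:1,Renocera_pallida:1):1):1,((Tetanocera_robusta:1,Tetanocera_annae:1):1,((Tetanocera_silvatica:1,Tetanocera_freyi:1):1,(((Tetanocera_plumosa:1,(Tetanocera_hyalipennis:1,Tetanocera_bergi:1):1):1,(Tetanocera_kerteszi:1,(Tetanocera_valida:1,(Tetanocera_clara:1,((Tetanocera_elata:1,Tetanocera_plebeja:1):1,(Tetanocera_arrogans:1,(Tetanocera_melanostigma:1,(Tetanocera_oxia:1,Tetanocera_rotundicornis:1):1):1):1):1):1):1):1):1,((Tetanocera_ferruginea:1,(Tetanocera_fuscinervis:1,Tetanocera_loewi:1):1):1,((Tetanocera_montana:1,(Tetanocera_phyllophora:1,Tetanocera_soror:1):1):1,((Tetanocera_amurensis:1,Tetanocera_vicina:1):1,(Tetanocera_obtusifibula:1,(Tetanocera_arnaudi:1,(Tetanocera_latifibula:1,Tetanocera_mesopora:1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1):1);
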