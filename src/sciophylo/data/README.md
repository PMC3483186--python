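# Packaged study data

`sciomyzidae_characters.tsv` — larval feeding group and habitat codings for
the 66 sampled species (64 sciomyzids, *Pelidnoptera nigripennis*
(Phaeomyiidae) and the *Drosophila melanogaster* outgroup), compiled from
the published life-history literature on snail-killing flies. Twelve
feeding states: ten sciomyzid behavioral groups plus the millipede
parasitoid and yeast/mold outgroup states. Habitat is aquatic/terrestrial;
*Tetanocera plumosa*, which occurs both in the water and on damp
shorelines, is coded `both`; the eleven species with unknown life cycles
are coded `?`.

`sciomyzidae_tree.nwk` — species-level rooted topology (one terminal per
species) transcribed from the published Bayesian consensus phylogeny of
this 5-gene data set, as described in its accompanying text: Sciomyzini
monophyletic, *Pelidnoptera* sister to a monophyletic Tetanocerini,
*Anticheta* and *Psacadina* the two basal-most tetanocerine lineages,
*Sepedon* diverging early in the aquatic core, *Limnia* rendered
polyphyletic by *Trypetoptera* and *Pherbina*, *Trypetoptera* by
*L. ottawensis*, *Renocera* by *Ethiolimnia* and *Dichetophora*, and the
four named *Tetanocera* clades (①: *robusta*+*annae* sister to the rest;
④: *silvatica*+*freyi* sister to ②+③; ② holding all five behavioral
groups; ③ with eight aquatic predators, one shoreline predator, one
terrestrial predator and two unknowns). The source figure is not available
in machine-readable form, so arrangements it leaves unstated (e.g. within
*Dictya*) are arbitrary, and branch lengths — unrecoverable from a printed
figure — are set to 1.0 throughout (unit-length variant). Analyses
sensitive to branch lengths should treat this tree as a topology, not a
chronogram.
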