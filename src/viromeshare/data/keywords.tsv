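# Functional keyword taxonomy, v1.
# category <TAB> comma-separated case-insensitive description keywords.
# A description matches a category when it contains any keyword as a
# substring. "hypothetical" applies only when no functional category
# matches. Holin is deliberately its own category: hole-forming timing
# proteins are not cell-wall hydrolases and must not inflate lysin counts.
capsid/head	capsid, head protein, head-tail, prohead
portal	portal
tail	tail fiber, tail protein, tail tape, tail spike, tailspike, tail assembly
baseplate	baseplate
sheath	sheath
collar	collar
integrase	integrase, site-specific recombinase, tyrosine recombinase, serine recombinase
lysin	lysin, endolysin, lysozyme, amidase, muramidase, glucosaminidase, peptidoglycan hydrolase
holin	holin
replication	replication, dna polymerase, primase, helicase, replisome, single-stranded dna-binding
transposition	transposase, transposition
restriction/modification	restriction endonuclease, methyltransferase, restriction enzyme, modification methylase
other	terminase, scaffolding, virion, structural protein, nuclease, ligase, kinase, protease, repressor, antirepressor, excisionase, rep protein, coat protein
hypothetical	hypothetical, uncharacterized, unknown function, putative protein
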