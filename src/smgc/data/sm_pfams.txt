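# PFAM domains treated as SM-specific when extending cluster borders.
# One accession per line; '#' starts a comment.  The set is editable:
# it contains the backbone core domains plus tailoring-enzyme domains
# recurrently found in characterized fungal secondary-metabolite
# clusters (oxidoreductases, methyltransferases, acyl/glycosyl
# transferases, oxygenases, transporters).
# backbone cores
PF00109  # beta-ketoacyl synthase, N-terminal
PF02801  # beta-ketoacyl synthase, C-terminal
PF00698  # acyltransferase
PF00550  # phosphopantetheine attachment (ACP/PCP)
PF08659  # ketoreductase
PF14765  # polyketide synthase dehydratase
PF00668  # condensation
PF00501  # AMP-binding (adenylation)
PF00975  # thioesterase
PF07993  # NAD-binding reductase (Male sterility domain)
PF11991  # tryptophan dimethylallyltransferase
PF06330  # trichodiene synthase (fungal terpene cyclase)
PF01397  # terpene synthase, N-terminal
PF03936  # terpene synthase, C-terminal
PF00494  # squalene/phytoene synthase
PF13243  # squalene-hopene cyclase
# tailoring enzymes
PF00067  # cytochrome P450
PF01494  # FAD-binding monooxygenase
PF08241  # methyltransferase domain
PF08242  # methyltransferase domain
PF13489  # methyltransferase domain
PF00891  # O-methyltransferase
PF00106  # short-chain dehydrogenase/reductase
PF00583  # GNAT acetyltransferase
PF01593  # flavin amine oxidase
PF03171  # 2OG-Fe(II) oxygenase
PF00155  # aminotransferase class I/II
PF00201  # UDP-glucuronosyl transferase
PF00296  # luciferase-like monooxygenase
PF05368  # NmrA-like
PF01073  # 3-beta hydroxysteroid dehydrogenase
PF07690  # major facilitator superfamily transporter
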