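# Default relation-expression synonym table: surface<TAB>normalized relation.
# Surfaces are case-insensitive literals; "***" is a wildcard capturing a
# maximal non-empty token run (e.g. a gene name plus variant).
for the prevention of	treats
for relief of the signs and symptoms	treats
for the treatment of	treats
as monotherapy of	treats
in combination with	synergized_by
coadministered with	synergized_by
avoid concurrent administration of	antagonized_by
avoid concomitant use of	antagonized_by
total daily doses	have_dosage
recommended dosage	have_dosage
with *** mutation	have_mutation
the presence of *** mutation	have_mutation
be homozygous for	have_mutation
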