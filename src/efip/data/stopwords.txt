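# Common-word stoplist for the protein-like token fallback.
# Tokens whose lower-cased form appears here are never emitted as
# pattern-derived protein mentions (lexicon entries always win).
the
a
an
and
or
but
nor
of
in
on
at
by
to
for
with
from
into
via
upon
between
among
within
through
during
after
before
while
when
where
whether
which
who
whose
that
this
these
those
their
its
his
her
our
we
they
it
is
are
was
were
be
been
being
has
have
had
can
could
may
might
will
would
shall
should
must
not
no
also
both
each
either
such
same
other
another
more
most
less
least
very
only
then
thus
hence
however
although
moreover
furthermore
therefore
here
there
first
second
third
finally
addition
data
study
studies
result
results
figure
figures
table
tables
fig
figs
et
al
cells
cell
cellular
protein
proteins
kinase
kinases
substrate
substrates
site
sites
residue
residues
phosphorylation
phosphorylated
phosphorylates
phosphorylate
dephosphorylation
phospho
unphosphorylated
nonphosphorylated
interaction
interactions
interact
interacts
interacted
interacting
binding
bind
binds
bound
association
associations
associate
associates
associated
associating
dissociation
dissociate
dissociates
dissociated
dissociating
complex
complexes
dimerization
dimerize
dimerizes
dimerized
affinity
precipitation
coprecipitation
precipitate
precipitates
precipitated
recruitment
recruit
recruits
recruited
release
released
releases
releasing
sequestering
sequestration
sequestered
sequester
sequesters
facilitates
facilitate
facilitated
facilitating
promotes
promote
promoted
promoting
enhances
enhance
enhanced
enhancing
increases
increase
increased
increasing
decreases
decrease
decreased
decreasing
reduces
reduce
reduced
reducing
abolishes
abolish
abolished
prevents
prevent
prevented
impairs
impair
impaired
inhibits
inhibit
inhibited
disrupts
disrupt
disrupted
induces
induce
induced
inducing
results
resulted
resulting
leads
lead
led
requires
required
require
suggests
suggest
suggested
shows
show
shown
showed
demonstrates
demonstrate
demonstrated
indicates
indicate
indicated
observed
observe
found
find
investigated
investigate
examined
examine
treatment
treated
response
mediated
dependent
independent
catalyzed
induced
expression
activity
activation
regulation
regulates
regulated
function
functional
level
levels
pathway
pathways
signaling
apoptosis
mitochondrial
injury
cytoplasmic
nuclear
nucleus
membrane
modification
form
forms
formation
role
effect
effects
ability
impact
event
events
assay
assays
analysis
anti
type
wild
mutant
mutants
domain
domains
motif
region
regions
family
terminal
amino
acid
acids
novel
human
mouse
rat
yeast
gene
genes
mrna
dna
rna
abstract
introduction
background
methods
materials
discussion
conclusion
conclusions
# appended
injury
stress
damage
mitochondrial
apoptosis
cytokine
serum
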