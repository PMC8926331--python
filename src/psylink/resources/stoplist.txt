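# Function-word stoplist: common prepositions, pronouns and articles.
# Drug names from the drug overview table are merged in at vocabulary
# build time (case-insensitive matching).
the
a
an
and
or
but
if
then
than
that
this
these
those
i
me
my
mine
myself
we
us
our
ours
ourselves
you
your
yours
yourself
yourselves
he
him
his
himself
she
her
hers
herself
it
its
itself
they
them
their
theirs
themselves
who
whom
whose
which
what
about
above
across
after
against
along
amid
among
around
at
before
behind
below
beneath
beside
besides
between
beyond
by
concerning
despite
down
during
except
for
from
in
inside
into
like
near
of
off
on
onto
out
outside
over
past
per
since
through
throughout
till
to
toward
towards
under
underneath
until
up
upon
via
with
within
without
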