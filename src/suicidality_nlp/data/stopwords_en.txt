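# Default English stop list for bag-of-words feature pruning.
# Negation and assertion cues (no, not, never, without, denies, ...) are
# deliberately NOT stop words: they carry the signal the classifiers need.
a
an
the
this
that
these
those
i
you
he
she
it
we
they
him
them
his
her
its
their
my
your
our
me
us
himself
herself
themselves
myself
am
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
having
do
does
did
done
of
in
on
at
by
for
with
from
into
about
after
before
over
under
during
since
while
as
to
and
or
so
yet
if
because
although
though
whether
will
would
can
could
shall
should
may
might
must
there
here
when
where
how
why
who
what
which
very
also
now
then
than
too
such
own
same
just
more
most
other
some
any
each
all
both
few
s
t
d
ll
m
re
ve
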