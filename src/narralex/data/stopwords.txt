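# narralex packaged English stopword list, version 1.
# One word per line; lines starting with '#' are comments.
a
an
the
and
but
or
nor
so
yet
if
because
although
while
when
where
why
how
what
which
who
whom
whose
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
she
her
hers
herself
he
him
his
himself
it
its
itself
they
them
their
theirs
themselves
am
is
are
was
were
be
been
being
have
has
had
having
do
does
did
doing
can
could
shall
should
may
might
must
would
to
of
in
for
with
on
at
from
by
about
as
into
like
over
after
before
under
above
below
between
through
during
out
off
up
down
again
further
then
once
here
there
all
any
both
each
few
more
most
other
some
such
only
own
same
than
very
just
too
also
not
no
never
none
nothing
cannot
can't
don't
won't
didn't
doesn't
isn't
wasn't
aren't
weren't
couldn't
wouldn't
shouldn't
i'm
i've
i'll
i'd
it's
that's
there's
he's
she's
we're
they're
you're
really
quite
still
even
ever
always
often
sometimes
now
get
got
go
going
went
come
came
say
said
says
know
knew
think
thought
make
made
see
saw
way
thing
time
day
year
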