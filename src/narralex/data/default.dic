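%
1	pos_tone
2	neg_tone
3	social
4	article
5	prep
6	ppron
7	ipron
8	auxverb
9	conj
10	adverb
11	negations
12	exclusive
%
good	1
great	1
happy	1
happi*	1
joy*	1
love*	1
hope*	1
glad	1
nice	1
better	1
best	1
wonderful	1
calm*	1
peace*	1
proud	1
laugh*	1
smile*	1
relief	1
comfort*	1
grateful	1
bad	2
sad*	2
fear*	2
afraid	2
lonel*	2
angry	2
anger	2
hate*	2
hurt*	2
pain*	2
worse	2
worst	2
terribl*	2
awful	2
cry	2
cried	2
scared	2
scary	2
anxious	2
anxiety	2
depress*	2
suffer*	2
friend*	3
famil*	3
people	3
person	3
talk*	3
listen*	3
social*	3
mother*	3
father*	3
brother*	3
sister*	3
parent*	3
doctor*	3
nurse*	3
therapist*	3
commun*	3
together	3
visit*	3
meet*	3
neighbor*	3
a	4
an	4
the	4
to	5
of	5
in	5
for	5
with	5
on	5
at	5
from	5
by	5
about	5
into	5
over	5
after	5
under	5
between	5
through	5
during	5
without	5	12
i	6
me	6
my	6
mine	6
myself	6
we	6
us	6
our	6
ours	6
ourselves	6
you	6
your	6
yours	6
yourself	6
yourselves	6
she	6
her	6
hers	6
herself	6
he	6
him	6
his	6
himself	6
they	6
them	6
their	6
theirs	6
themselves	6
it	7
its	7
itself	7
this	7
that	7
these	7
those	7
something	7
anything	7
everything	7
somebody	7
anybody	7
everybody	7
am	8
is	8
are	8
was	8
were	8
be	8
been	8
being	8
have	8
has	8
had	8
do	8
does	8
did	8
can	8
could	8
will	8
would	8
shall	8
should	8
may	8
might	8
must	8
and	9
but	9	12
or	9	12
because	9
so	9
while	9
when	9
although	9
if	9
very	10
really	10
just	10
too	10
also	10
quite	10
always	10
often	10
again	10
still	10
then	10
now	10
here	10
there	10
not	11
no	11
never	11
none	11
nothing	11
cannot	11
can't	11
don't	11
won't	11
didn't	11
doesn't	11
isn't	11
wasn't	11
aren't	11
weren't	11
couldn't	11
wouldn't	11
shouldn't	11
except	12
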