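a
about
all
also
an
and
any
are
as
at
be
been
but
by
can
could
do
does
for
from
had
has
have
if
in
into
is
it
its
may
more
most
not
of
on
or
other
our
she
some
such
than
that
the
their
then
there
these
they
this
to
was
we
were
which
will
with
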