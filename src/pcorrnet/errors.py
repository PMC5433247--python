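"""Exception hierarchy for pcorrnet.

All errors raised deliberately by the library derive from :class:`PcorrError`
so callers (and the CLI) can distinguish usage errors from bugs.
"""


class PcorrError(Exception):
    """Base class for all pcorrnet errors."""


class InputError(PcorrError, ValueError):
    """Invalid argument values (shape mismatches, out-of-range parameters)."""


class StationarityError(InputError):
    """Simulation state matrix has spectral radius >= 1 (no steady state)."""


class ParseError(PcorrError, ValueError):
    """Malformed delimited-text input file."""
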