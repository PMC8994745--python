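"""Exception hierarchy.

Errors fall into two families, mirroring the CLI exit-code contract:
input/validation problems (exit code 2) and algorithmic infeasibility
(exit code 3) — a structurally valid input for which no restraint
selection or chaining exists.
"""


class RestraintError(Exception):
    """Base class for all package-specific errors."""


class InputError(RestraintError):
    """Invalid input: unparsable file, bad parameter, schema violation."""


class FormatError(InputError):
    """A structure or restraint file does not parse under its format."""


class ComplexityGuardError(InputError):
    """A brute-force enumeration would exceed the configured subset cap."""


class InfeasibleError(RestraintError):
    """No solution exists for a structurally valid input."""


class NoCandidatesError(InfeasibleError):
    """No cross-molecule atom pair satisfies the distance cutoff."""


class ChainingError(InfeasibleError):
    """No branch-free spanning chain exists over the available pairs."""


class RingClosureError(ChainingError):
    """The two chain endpoints cannot be restrained to each other."""
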