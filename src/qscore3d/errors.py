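"""Exception hierarchy.

Input problems (unreadable files, malformed tables) raise :class:`InputError`
subclasses; failures of the numerics themselves (zero variance, rank-deficient
fits, empty windows) raise :class:`ComputationError`.  The CLI maps the two
branches to exit codes 2 and 3.
"""


class QScoreError(Exception):
    """Base class for all package errors."""


class InputError(QScoreError):
    """A user-supplied input could not be read or validated."""


class MapFormatError(InputError):
    """Density map file is missing, truncated or not MRC/CCP4."""


class ModelFormatError(InputError):
    """Coordinate file could not be parsed as PDB or mmCIF."""


class ComputationError(QScoreError):
    """A computation could not be carried out on otherwise valid input."""


class ExtrapolationWarning(UserWarning):
    """Statistical model evaluated outside its calibrated resolution domain."""
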