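"""Exception hierarchy used across the pipeline.

Every stage raises a subclass of :class:`HistovolError` so the CLI can tag
failures with the stage that produced them.
"""


class HistovolError(Exception):
    """Base class for all histovol errors."""


class ConfigError(HistovolError, ValueError):
    """Invalid configuration: unknown key, out-of-range value, bad field."""


class FormatError(HistovolError, ValueError):
    """Malformed input file (manifest, landmark file, VTK header...)."""


class RegistrationError(HistovolError, ValueError):
    """Degenerate landmarks or an unalignable slice."""


class SegmentationError(HistovolError, ValueError):
    """Invalid segmentation input (no tissue, bad seed, bad factor...)."""
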