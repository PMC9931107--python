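"""Package-wide exception types."""


class VocemoError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(VocemoError, ValueError):
    """A preset, corpus spec, kernel or config violates its invariants."""


class AliasingError(VocemoError, ValueError):
    """Requested harmonics would exceed the Nyquist frequency."""


class UnsupportedFormatError(VocemoError, ValueError):
    """Audio file is not RIFF PCM WAV, or is empty."""


class FeatureExtractionError(VocemoError, ValueError):
    """Feature extraction is impossible (e.g. no voiced frames)."""


class UndefinedKappaError(VocemoError, ValueError):
    """Cohen's kappa is undefined (expected agreement equals 1, or the
    target category is absent from both raters)."""


class CollinearityError(VocemoError, ValueError):
    """Design matrix is rank deficient."""
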