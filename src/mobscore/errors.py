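"""Exception hierarchy for mobscore."""


class MobscoreError(Exception):
    """Base class for all mobscore errors."""


class ConfigurationError(MobscoreError):
    """Invalid registry or simulation configuration."""


class MeasurementError(MobscoreError):
    """A raw measurement violates its instrument's contract."""


class NormLookupError(MobscoreError):
    """No (or no unique) norm stratum matches the participant."""


class UndefinedScoreError(MobscoreError):
    """A dimension score is undefined (zero assessed items)."""


class CohortFormatError(MobscoreError):
    """A cohort table fails to parse or validate."""
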