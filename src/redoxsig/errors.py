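"""Exception hierarchy for the redoxsig pipeline."""


class RedoxSigError(Exception):
    """Base class for all redoxsig errors."""


class ConfigError(RedoxSigError):
    """Invalid configuration value; message names the offending field."""


class SchemaError(RedoxSigError):
    """Input table does not match the expected schema (e.g. unknown channel)."""


class DesignError(RedoxSigError):
    """Inconsistent plex/channel design (e.g. duplicate sample across plexes)."""
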