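class ConfigError(ValueError):
    """Raised when a parameter object is internally inconsistent."""
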