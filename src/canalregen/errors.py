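"""Exception hierarchy for the canal-regeneration pipeline."""


class CanalRegenError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CanalRegenError):
    """An input file could not be read or has an unsupported format."""


class MetadataError(CanalRegenError):
    """A volume file lacks required geometric metadata (spacing/origin)."""


class GeometryError(CanalRegenError):
    """Degenerate or inconsistent geometry (centerline, landmarks, sections)."""


class SpecError(CanalRegenError):
    """An invalid phantom specification."""


class InputError(CanalRegenError):
    """Invalid analytic input (empty section list, too few stations, ...)."""
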