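"""Exception hierarchy.

The CLI maps these onto exit codes: validation failures exit 2,
configuration failures exit 3.
"""


class DisconnectomeError(Exception):
    """Base class for all package errors."""


class ValidationError(DisconnectomeError):
    """Inputs are structurally inconsistent (shape mismatch, non-binary mask,
    weights out of range, endpoint pair missing from the reference connectome)."""


class ConfigurationError(DisconnectomeError):
    """A run or cohort configuration is infeasible (more parcels than voxels,
    lesion sphere entirely outside the grid, missing inputs)."""


class DegenerateInputError(DisconnectomeError):
    """An operation is undefined on this input (zero baseline volume,
    constant image for NMI, all-zero baseline connectome)."""


class GenerationError(DisconnectomeError):
    """The synthetic generator exhausted its retry budget."""
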