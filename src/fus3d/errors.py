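"""Exception types raised by the fus3d pipeline stages."""


class Fus3dError(Exception):
    """Base class for all fus3d errors."""


class SegmentationError(Fus3dError):
    """Level-set evolution failed (contour vanished or numerics diverged)."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message if iteration is None else f"{message} (iteration {iteration})")
        self.iteration = iteration


class GvfDivergenceError(Fus3dError):
    """GVF diffusion produced a non-finite field."""

    def __init__(self, message: str, iteration: int):
        super().__init__(f"{message} (iteration {iteration})")
        self.iteration = iteration


class RegistrationError(Fus3dError):
    """Multi-view registration failed (no overlap or optimizer breakdown)."""


class ReconstructionError(Fus3dError):
    """3D reconstruction / volume estimation failed."""
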