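"""Exception hierarchy for the biocontinuum package."""


class BiocontinuumError(Exception):
    """Base class for all package-specific errors."""


class NegativeProbability(BiocontinuumError, ValueError):
    """A probability entry is below the negativity tolerance."""


class NotNormalized(BiocontinuumError, ValueError):
    """Probability entries do not sum to one within tolerance."""


class NonPositiveCount(BiocontinuumError, ValueError):
    """A population abundance is zero or negative."""


class DimensionMismatch(BiocontinuumError, ValueError):
    """Vectors or matrices with incompatible lengths were combined."""


class IntegrationFailure(BiocontinuumError, RuntimeError):
    """The ODE solver did not converge at the requested tolerances."""


class SingularSystem(BiocontinuumError, RuntimeError):
    """The interior-equilibrium linear system has no unique solution."""


class SupportMismatch(BiocontinuumError, ValueError):
    """q puts mass where p is (numerically) zero; KL divergence is infinite."""


class NonPositiveSigma(BiocontinuumError, ValueError):
    """A Gaussian-manifold point has sigma <= 0."""


class BoundaryPoint(BiocontinuumError, ValueError):
    """Simplex metric requested at a point with a vanishing coordinate."""


class AsymmetricPayoff(BiocontinuumError, ValueError):
    """A symmetric payoff matrix was required but not supplied."""


class StalledFlow(BiocontinuumError, RuntimeError):
    """Natural-gradient flow could not decrease the objective at minimum step."""


class SchemaError(BiocontinuumError, ValueError):
    """A scenario JSON document violates the schema."""


class FormatError(BiocontinuumError, ValueError):
    """A trajectory CSV file is malformed."""


class GridTooCoarseWarning(UserWarning):
    """Action quadrature changed noticeably under grid refinement."""
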