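"""Exception hierarchy for spotcoloc.

All package-specific failures derive from :class:`SpotColocError` so callers
can catch one base class; geometry and statistics failures get narrower types
because tests and pipelines branch on them.
"""


class SpotColocError(Exception):
    """Base class for all spotcoloc errors."""


class FormatError(SpotColocError, ValueError):
    """A file did not conform to its expected dialect (MTX/TSV/CSV)."""


class DataConsistencyError(SpotColocError, ValueError):
    """Structurally valid inputs that contradict each other or an invariant."""


class GraphError(SpotColocError, ValueError):
    """Invalid graph construction input or use."""


class TooFewPointsError(GraphError):
    """Delaunay triangulation needs at least 3 points."""


class CollinearPointsError(GraphError):
    """All points lie on a single line; no 2D triangulation exists."""


class DuplicatePointsError(GraphError):
    """Two or more points share identical coordinates."""


class IsolatedVertexError(GraphError):
    """A vertex without neighbors cannot be neighborhood-averaged."""


class UndefinedCorrelationError(SpotColocError, ValueError):
    """Correlation is undefined because one input has zero variance."""


class ConfigError(SpotColocError, ValueError):
    """Invalid run or simulation configuration; carries all problems at once."""

    def __init__(self, problems):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
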