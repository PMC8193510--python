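"""Exception types shared across the pipeline."""


class TreescapeError(Exception):
    """Base class for all treescape errors."""


class SchemaError(TreescapeError):
    """Inputs disagree on node labels, subject ids, or table layout."""


class InvalidSizeError(TreescapeError):
    """A size precondition (node count, group count, ...) is violated."""


class ZeroVarianceError(TreescapeError):
    """A time series with zero variance cannot be correlated."""

    def __init__(self, nodes):
        self.nodes = list(nodes)
        super().__init__(f"zero-variance time series for node(s): {self.nodes}")


class DisconnectedGraphError(TreescapeError):
    """The positive-weight graph does not connect all nodes."""

    def __init__(self, components):
        self.components = [sorted(c, key=str) for c in components]
        super().__init__(
            f"positive-edge graph is disconnected: {len(self.components)} components "
            f"(sizes {[len(c) for c in self.components]})"
        )


class UndefinedMetricError(TreescapeError):
    """A tree metric is undefined for this input (e.g. n < 3)."""


class InsufficientDataError(TreescapeError):
    """Too few support points to fit the requested model."""


class GenerationError(TreescapeError):
    """Synthetic-data generation failed to satisfy its contract."""
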