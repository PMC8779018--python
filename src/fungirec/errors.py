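"""Exception hierarchy shared across the package."""


class FungirecError(Exception):
    """Base class for all package-specific errors."""


class DegenerateRowError(FungirecError):
    """A score row has no positive mass and cannot be normalized."""

    def __init__(self, rows):
        self.rows = list(rows)
        super().__init__(f"rows with zero total mass cannot be normalized: {self.rows}")


class UnsupportedClassError(FungirecError):
    """A class has zero prior probability but positive posterior mass."""

    def __init__(self, species):
        self.species = list(species)
        super().__init__(
            "train prior is zero for classes with positive posterior mass: "
            f"{self.species}"
        )


class AlignmentError(FungirecError):
    """Two per-observation structures do not describe the same observations."""


class ShapeError(FungirecError):
    """A vector or matrix does not match the expected label-space width."""


class UnknownSpeciesError(FungirecError):
    """A label refers to a species outside the label space."""

    def __init__(self, labels):
        self.labels = sorted(set(labels))
        super().__init__(f"unknown species: {self.labels}")


class DegenerateCropError(FungirecError):
    """A fractional crop collapses to an empty pixel rectangle."""


class ConfigError(FungirecError):
    """Invalid run configuration (bad stage chain, bad parameters)."""


class ParseError(FungirecError):
    """A data file could not be parsed; carries the offending location."""

    def __init__(self, message, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f":{line}]" if line is not None else "]")
        super().__init__(message + loc)
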