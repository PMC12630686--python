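"""Exception hierarchy for glueprint."""


class GlueprintError(Exception):
    """Base class for all package errors."""


class StructureParseError(GlueprintError):
    """The input file could not be parsed as PDB/mmCIF."""


class EmptyModelError(GlueprintError):
    """No atoms remained after loading and filtering."""


class EmptySelectionError(GlueprintError):
    """A subunit selection matched zero atoms."""


class PartitionError(GlueprintError):
    """Partition subunits overlap or are otherwise inconsistent."""


class ParameterError(GlueprintError):
    """Surface/analysis parameters outside their valid range."""


class PreconditionError(GlueprintError):
    """An operation was called before its inputs were prepared."""


class DegenerateGeometryError(GlueprintError):
    """Too few or collinear points for a geometric fit."""


class LigandCountError(GlueprintError):
    """Number of ligand copies differs from what the operation requires."""


class CorrespondenceError(GlueprintError):
    """Atom/residue correspondence between two selections failed."""
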