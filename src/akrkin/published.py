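"""Convenience constructors for published parameter sets."""

from __future__ import annotations

from . import constants
from .mechanism import MechanismParams


def published_params(compound: int, enzyme_id: str) -> MechanismParams:
    """MechanismParams for one published compound/isoform combination.

    Chooses the model variant from which constants were determined: a
    composite constant implies ``parabolic``; all irreversible rates zero
    implies ``reversible_only``; otherwise ``full``.
    """
    vals = constants.INHIBITION_CONSTANTS[compound][enzyme_id]
    shared = constants.SHARED_CONSTANTS[enzyme_id]
    kw = {k: v for k, v in vals.items() if v is not None}
    if "composite2" in kw or "composite3" in kw:
        variant = "parabolic"
    elif kw.get("k_plus2", 0.0) == 0.0 and kw.get("k_plus3", 0.0) == 0.0:
        variant = "reversible_only"
        kw.pop("k_plus2", None)
        kw.pop("k_plus3", None)
    else:
        variant = "full"
    return MechanismParams(**shared, **kw, variant=variant)
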