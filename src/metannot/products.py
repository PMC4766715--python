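"""Product-name assignment decision tree.

Branches, in order:

1. ``cog_name`` — the gene has a COG, the hit identity is >= 20% and
   the alignment covers >= 70% of the COG consensus length: the COG
   name is the product. Names that are "uncharacterized conserved
   protein" or contain "predicted" (case-insensitive) are reformatted
   as "COG name - COG ID".
2. ``cog_via_pfam`` — the COG hit fails those thresholds but (COG, one
   of the gene's Pfams) appears in the COG-Pfam correspondence table:
   the COG name is still used (same reformat rule).
3. ``pfam_name`` — no COG-derived name; the gene's strongest Pfam's
   name is the product.
4. ``hypothetical`` — no family evidence at all: "hypothetical protein"
   (conventional default; the trace makes the fall-through explicit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

COG_MIN_IDENTITY = 20.0
COG_MIN_ALN_FRACTION = 0.70
FALLBACK_NAME = "hypothetical protein"

BRANCH_COG = "cog_name"
BRANCH_COG_PFAM = "cog_via_pfam"
BRANCH_PFAM = "pfam_name"
BRANCH_HYPOTHETICAL = "hypothetical"


@dataclass
class NamingContext:
    """Evidence available to name one gene."""

    cog_id: str | None = None
    cog_identity: float = 0.0
    cog_alignment_length: int = 0
    pfam_accessions: list[str] = field(default_factory=list)  # strongest first
    cog_meta: dict[str, tuple[str, int]] = field(default_factory=dict)
    pfam_meta: dict[str, tuple[str, int]] = field(default_factory=dict)
    cog_pfam: set[tuple[str, str]] = field(default_factory=set)


def _format_cog_name(cog_id: str, name: str) -> str:
    low = name.lower()
    if low == "uncharacterized conserved protein" or "predicted" in low:
        return f"{name} - {cog_id}"
    return name


def assign_product_name(ctx: NamingContext) -> tuple[str, str]:
    """Return (product name, branch code); exactly one branch fires."""
    if ctx.cog_id is not None and ctx.cog_id in ctx.cog_meta:
        name, consensus_len = ctx.cog_meta[ctx.cog_id]
        thresholds_met = (
            ctx.cog_identity >= COG_MIN_IDENTITY
            and ctx.cog_alignment_length >= COG_MIN_ALN_FRACTION * consensus_len
        )
        if thresholds_met:
            return _format_cog_name(ctx.cog_id, name), BRANCH_COG
        if any((ctx.cog_id, acc) in ctx.cog_pfam for acc in ctx.pfam_accessions):
            return _format_cog_name(ctx.cog_id, name), BRANCH_COG_PFAM
    for acc in ctx.pfam_accessions:
        if acc in ctx.pfam_meta:
            return ctx.pfam_meta[acc][0], BRANCH_PFAM
    return FALLBACK_NAME, BRANCH_HYPOTHETICAL
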