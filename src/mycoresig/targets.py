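"""Direct-target derivation: intersecting binding and response evidence.

A direct target must be bound, transcriptionally responsive (nuclear
run-on), and changed at steady-state mRNA, all in the same direction;
discordant genes are excluded.  The core signature is then the intersection
of one context's induced targets with binding evidence from every other
context, finishing with an ortholog-mapped cross-species binding filter.
Every operation appends a provenance record (rule, input sizes, output
size) so the derivation chain is auditable.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .containers import CoreSignature, DifferentialResult, OrthologMap, TargetSet

__all__ = [
    "normalize_gene_id",
    "normalize_gene_set",
    "consensus_bound",
    "direct_targets",
    "shared_upregulated",
    "intersect_core",
    "cell_restricted",
]

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_gene_id(gene_id: str) -> str:
    """Canonical gene identity: case-folded, version suffix stripped."""
    return _VERSION_SUFFIX.sub("", gene_id.strip()).upper()


def normalize_gene_set(genes: Iterable[str]) -> set[str]:
    return {normalize_gene_id(g) for g in genes}


def _prov(step: str, inputs: dict[str, int], output_size: int) -> dict:
    return {"step": step, "inputs": inputs, "output_size": output_size}


def consensus_bound(
    bound_1: Iterable[str], bound_2: Iterable[str], provenance: list[dict] | None = None
) -> set[str]:
    """Genes bound by both antibodies (set intersection, with provenance)."""
    s1, s2 = set(bound_1), set(bound_2)
    out = s1 & s2
    if provenance is not None:
        provenance.append(
            _prov("consensus_bound", {"antibody_1": len(s1), "antibody_2": len(s2)}, len(out))
        )
    return out


def direct_targets(
    context: str,
    bound: Iterable[str],
    anro: DifferentialResult,
    rna: DifferentialResult,
) -> TargetSet:
    """Bound ∩ transcriptional response ∩ steady-state change, per direction.

    induced = bound ∩ anro-up ∩ rna-up; repressed = bound ∩ anro-down ∩
    rna-down.  Genes whose run-on and RNA directions disagree drop out by
    construction.  The run-on and RNA tables must cover the same gene
    universe.
    """
    bound = set(bound)
    anro_universe = set(anro.table.index)
    rna_universe = set(rna.table.index)
    if anro_universe != rna_universe:
        offending = sorted(anro_universe ^ rna_universe)
        raise ValueError(f"run-on/RNA gene universes differ: {offending[:10]}")
    extra = bound - anro_universe
    if extra:
        raise ValueError(f"bound genes outside expression universe: {sorted(extra)[:10]}")

    induced = bound & anro.up & rna.up
    repressed = bound & anro.down & rna.down
    provenance = [
        _prov(
            "direct_targets",
            {
                "bound": len(bound),
                "anro_up": len(anro.up),
                "anro_down": len(anro.down),
                "rna_up": len(rna.up),
                "rna_down": len(rna.down),
            },
            len(induced) + len(repressed),
        ),
        _prov("induced", {"bound∩anro_up∩rna_up": len(induced)}, len(induced)),
        _prov("repressed", {"bound∩anro_down∩rna_down": len(repressed)}, len(repressed)),
    ]
    return TargetSet(context, induced, repressed, bound, provenance).validate()


def shared_upregulated(
    targets_ctx1: TargetSet,
    bound_ctx2: Iterable[str],
    expressed_ctx2: Iterable[str],
    provenance: list[dict] | None = None,
) -> set[str]:
    """Induced targets of context 1 also bound and driver-responsive in context 2."""
    b2, e2 = set(bound_ctx2), set(expressed_ctx2)
    out = targets_ctx1.induced & b2 & e2
    if provenance is not None:
        provenance.append(
            _prov(
                "shared_upregulated",
                {
                    f"{targets_ctx1.context}_induced": len(targets_ctx1.induced),
                    "ctx2_bound": len(b2),
                    "ctx2_expressed": len(e2),
                },
                len(out),
            )
        )
    return out


def intersect_core(
    shared: Iterable[str],
    bound_sets: Sequence[Iterable[str]],
    ortholog: OrthologMap,
    mouse_bound: Iterable[str],
    contexts: Sequence[str] | None = None,
) -> CoreSignature:
    """Cross-context, cross-species core signature.

    Stage 1 intersects the shared up-regulated set with every additional
    bound set; stage 2 keeps genes whose murine ortholog is bound in mouse
    cells.  The stage sizes are recorded in provenance.
    """
    if len(bound_sets) < 1:
        raise ValueError("need at least one additional bound set")
    shared = set(shared)
    stage1 = set(shared)
    sizes = {"shared": len(shared)}
    for i, bs in enumerate(bound_sets):
        bs = set(bs)
        sizes[f"bound_set_{i+1}"] = len(bs)
        stage1 &= bs
    mouse_bound = set(mouse_bound)
    stage2 = {
        g for g in stage1 if ortholog.get(g) is not None and ortholog.get(g) in mouse_bound
    }
    provenance = [
        _prov("intersect_core_stage1", sizes, len(stage1)),
        _prov(
            "intersect_core_stage2",
            {"stage1": len(stage1), "mouse_bound": len(mouse_bound)},
            len(stage2),
        ),
    ]
    ctx = list(contexts) if contexts is not None else []
    return CoreSignature(sorted(stage2), ctx, provenance).validate()


def cell_restricted(
    targets_a: TargetSet,
    bound_b: Iterable[str],
    response_a: Iterable[str] | None = None,
    direction_split: tuple[Iterable[str], Iterable[str]] | None = None,
) -> TargetSet:
    """Targets specific to context A: responsive and bound in A, not bound in B.

    ``response_a`` defaults to A's induced ∪ repressed targets.  The result
    splits by direction using A's own induced/repressed labels (or an
    explicit ``direction_split`` of (up, down) sets).
    """
    bound_b = set(bound_b)
    if response_a is None:
        response_a = targets_a.induced | targets_a.repressed
    response_a = set(response_a)
    restricted = (response_a & targets_a.bound) - bound_b
    if direction_split is not None:
        up, down = (set(direction_split[0]), set(direction_split[1]))
    else:
        up, down = targets_a.induced, targets_a.repressed
    induced = restricted & up
    repressed = restricted & down
    provenance = [
        _prov(
            "cell_restricted",
            {
                "response_A": len(response_a),
                "bound_A": len(targets_a.bound),
                "bound_B": len(bound_b),
            },
            len(restricted),
        )
    ]
    return TargetSet(
        f"{targets_a.context}-restricted", induced, repressed,
        targets_a.bound - bound_b, provenance,
    ).validate()
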