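"""End-to-end per-circuit analysis: pseudosymmetries -> group -> sectors
-> blocks -> circulant filters -> significance -> baselines.

The report mirrors the per-circuit summary table of the analysis: one row
per subgroup with its sector, uncertainty constant eps, group name and
p-value, plus the block/filter inventory of the idealized circuit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .circuits import Circuit, CircuitError, subcircuit
from .symmetry import (PLAUSIBILITY_BOUND, Permutation, epsilon,
                       find_pseudosymmetries)
from .group_structure import PermGroup, closure, factorize
from .idealization import idealize_report
from .imprimitivity import block_systems, orbits, sector_block_candidates
from .circulant import (circulant_eigen, detect_block_circulant,
                        detect_circulant, nearest_pseudocirculant)
from .significance import subgroup_pvalue
from . import baselines as _baselines

__all__ = ["AnalysisConfig", "analyze", "report_to_markdown"]


@dataclass(frozen=True)
class AnalysisConfig:
    eps_max: float = PLAUSIBILITY_BOUND
    null_samples: int = 0          # 0 disables p-values (they are costly)
    seed: int = 0
    denominator: str = "circuit"
    run_baselines: bool = True
    annotations: dict[str, str] | None = None   # neuron -> category


def _perm_json(p: Permutation) -> list[list[str]]:
    return [list(c) for c in p.cycles()]


def analyze(c: Circuit, config: AnalysisConfig | None = None) -> dict:
    """Run the full symmetry analysis of one circuit.

    Returns a JSON-serializable report; fully deterministic for a fixed
    circuit, config and seed.
    """
    cfg = config or AnalysisConfig()
    report: dict = {
        "circuit": {
            "n": c.n,
            "labels": list(c.labels),
            "directed": c.directed,
            "link_type": c.link_type,
            "total_weight": c.total_weight,
        },
        "config": {
            "eps_max": cfg.eps_max,
            "null_samples": cfg.null_samples,
            "seed": cfg.seed,
            "denominator": cfg.denominator,
        },
    }

    # 1. pseudosymmetry search
    try:
        found = find_pseudosymmetries(c, cfg.eps_max,
                                      denominator=cfg.denominator)
    except CircuitError as exc:
        raise CircuitError(f"[pseudosymmetry stage] {exc}") from exc
    report["pseudosymmetries"] = {
        "n_exact": len(found["exact"]),
        "swaps": [
            {"cycles": _perm_json(ps.perm), "eps": ps.eps, "norm": ps.norm}
            for ps in found["swaps"]
        ],
        "templates": [
            {"template": t.template, "sector": list(t.sector),
             "eps": t.eps, "eps_mean": t.eps_mean,
             "generators": [_perm_json(g) for g in t.generators]}
            for t in found["templates"]
        ],
    }

    # 2. pseudosymmetry group: closure of accepted template generators
    #    together with the exact symmetry group
    from .group_structure import GroupError

    gens = [g for t in found["templates"] for g in t.generators]
    exact_group = found.get("exact_group")
    if exact_group is not None:
        gens.extend(exact_group.generators)
    elif found["exact"]:
        gens.extend(found["exact"])
    note = None
    if gens:
        try:
            G = closure(gens)
        except GroupError as exc:
            # an over-permissive eps_max can make the template closure
            # explode; fall back to the exact group and keep the
            # candidates on record
            G = exact_group if exact_group is not None \
                else PermGroup.trivial(c.labels)
            note = f"template closure capped ({exc}); using exact group"
    else:
        G = PermGroup.trivial(c.labels)
    report["group"] = {"order": G.order,
                       "generators": [_perm_json(g) for g in G.generators]}
    if note:
        report["group"]["note"] = note

    # 3. idealization: the eps -> 0 circuit on which G is exact
    try:
        ideal_rep = idealize_report(c, G)
    except CircuitError as exc:
        raise CircuitError(f"[idealization stage] {exc}") from exc
    ideal = ideal_rep.ideal
    report["idealization"] = {
        "distance": ideal_rep.distance,
        "distance_fraction": ideal_rep.distance_fraction,
    }

    # 4. factorization of the ideal circuit's pseudosymmetry group
    fact = factorize(G)
    rows = []
    factors_json = []
    for fac in fact.factors:
        gen_eps = [epsilon(c, g, cfg.denominator).eps
                   for g in fac.subgroup.generators] or [0.0]
        row = {
            "sector": list(fac.sector),
            "subgroup": fac.name,
            "order": fac.subgroup.order,
            "eps": max(gen_eps),
            "eps_mean": float(np.mean(gen_eps)),
        }
        if cfg.null_samples > 0:
            try:
                null = subgroup_pvalue(
                    c, fac.name, len(fac.sector), row["eps"],
                    R=cfg.null_samples, seed=cfg.seed,
                    denominator=cfg.denominator,
                )
                row["p_value"] = null.p
                row["p_guarded"] = null.p_guarded
            except CircuitError as exc:
                row["p_value"] = None
                row["p_note"] = str(exc)
        rows.append(row)

        # 5. blocks of imprimitivity and circulant structure per factor
        fac_json = dict(row)
        fac_json["generators"] = [_perm_json(g)
                                  for g in fac.subgroup.generators]
        fac_orbits = [sorted(o) for o in orbits(fac.subgroup) if len(o) > 1]
        fac_json["orbits"] = fac_orbits
        fac_json["block_systems"] = []
        transitive = len(fac_orbits) == 1 and \
            set(fac_orbits[0]) == set(fac.sector)
        if transitive:
            systems = block_systems(fac.subgroup, fac_orbits[0])
            fac_json["primitive"] = not systems
        else:
            # intransitive factor (e.g. a single involution): enumerate
            # valid conjugate splits of the whole sector instead
            systems = sector_block_candidates(ideal, fac.subgroup, fac.sector)
            fac_json["primitive"] = None
        for bs in systems:
            entry = {"blocks": [list(b) for b in bs.blocks],
                     "block_size": bs.block_size}
            entry.update(_block_structure(ideal, bs.blocks))
            fac_json["block_systems"].append(entry)
        factors_json.append(fac_json)
    report["factorization"] = {
        "n_factors": len(fact.factors),
        "residual": fact.residual,
        "factors": factors_json,
    }
    report["table"] = rows

    # 6. baselines
    if cfg.run_baselines:
        report["baselines"] = _baseline_block(c, fact, cfg)

    return report


def _block_structure(ideal: Circuit, blocks: Sequence[Sequence[str]]) -> dict:
    """Circulant profiles of each block and the block-circulant check."""
    out: dict = {"block_profiles": []}
    for blk in blocks:
        sub = subcircuit(ideal, list(blk))
        prof = detect_circulant(sub.weights, sub.labels)
        if prof is None:
            prof = nearest_pseudocirculant(sub.weights, sub.labels)
        entry = {
            "labels": list(blk),
            "first_row": list(prof.first_row),
            "ordering": list(prof.ordering),
            "filter_class": prof.filter_class,
            "deviation": prof.deviation,
        }
        if prof.deviation == 0:
            eig = circulant_eigen(prof)
            entry["eigenvalues"] = [
                float(v.real) if not np.iscomplexobj(np.asarray(v)) or
                getattr(v, "imag", 0) == 0 else complex(v)
                for v in eig.eigenvalues
            ]
        out["block_profiles"].append(entry)
    if len(blocks) > 1 and len({len(b) for b in blocks}) == 1:
        bc = _aligned_block_circulant(ideal, blocks, out["block_profiles"])
        out["block_circulant"] = bc is not None
        if bc is not None:
            out["block_components"] = [b.tolist() for b in bc.block_matrices]
            out["block_order"] = [list(b) for b in bc.block_order]
    return out


def _rotations_and_reflections(seq: tuple) -> list[tuple]:
    l = len(seq)
    rots = [seq[k:] + seq[:k] for k in range(l)]
    rev = seq[::-1]
    rots += [rev[k:] + rev[:k] for k in range(l)]
    return rots


def _aligned_block_circulant(ideal: Circuit, blocks, profiles):
    """Block-circulant check; when every block has an exact circulant
    profile, the profiles' realizing orders are used and non-first blocks
    are additionally tried in all rotations/reflections (a circulant
    ordering is only unique up to the dihedral action on the cycle)."""
    import itertools

    bc = detect_block_circulant(ideal.weights, ideal.labels, blocks)
    if bc is not None:
        return bc
    if any(p["deviation"] != 0 for p in profiles):
        return None
    base = [tuple(p["ordering"]) for p in profiles]
    choice_sets = [[base[0]]] + [_rotations_and_reflections(o)
                                 for o in base[1:]]
    for combo in itertools.product(*choice_sets):
        bc = detect_block_circulant(ideal.weights, ideal.labels, list(combo))
        if bc is not None:
            return bc
    return None


def _baseline_block(c: Circuit, fact, cfg: AnalysisConfig) -> dict:
    sectors = [set(f.sector) for f in fact.factors]
    covered = set().union(*sectors) if sectors else set()
    partition = [frozenset(s) for s in sectors]
    partition += [frozenset({lab}) for lab in c.labels if lab not in covered]
    out: dict = {"sector_partition": [sorted(p) for p in partition]}
    try:
        modular = _baselines.modularity_partition(c, seed=cfg.seed)
        out["modularity"] = {
            "communities": [sorted(p) for p in modular],
            "agreement_with_sectors":
                _baselines.partition_agreement(partition, modular),
        }
    except CircuitError as exc:
        out["modularity"] = {"error": str(exc)}
    try:
        cent = _baselines.eigenvector_centrality(c)
        out["eigenvector_centrality"] = {
            lab: round(v, 6) for lab, v in cent.items()
        }
    except CircuitError as exc:
        out["eigenvector_centrality"] = {"error": str(exc)}
    if cfg.annotations:
        cats: dict[str, set[str]] = {}
        for lab in c.labels:
            cats.setdefault(cfg.annotations.get(lab, "unannotated"),
                            set()).add(lab)
        ann_partition = [frozenset(v) for v in cats.values()]
        out["annotation_agreement"] = _baselines.partition_agreement(
            partition, ann_partition)
    return out


def report_to_markdown(report: dict) -> str:
    """Compact Markdown rendering of the analysis report."""
    lines = []
    circ = report["circuit"]
    lines.append(f"# Circuit analysis ({circ['n']} neurons, "
                 f"{circ['link_type']}, M = {circ['total_weight']})")
    lines.append("")
    lines.append("| sector | eps | subgroup | p-value |")
    lines.append("|---|---|---|---|")
    for row in report["table"]:
        p = row.get("p_value")
        lines.append(
            f"| ({', '.join(row['sector'])}) "
            f"| {100 * row['eps']:.1f}% "
            f"| {row['subgroup']} "
            f"| {'' if p is None else p} |"
        )
    lines.append("")
    fct = report["factorization"]
    lines.append(f"Factorization: {fct['n_factors']} normal subgroups"
                 + (" (residual coupling!)" if fct["residual"] else "")
                 + "; group order "
                 + str(report["group"]["order"]) + ".")
    lines.append("")
    for fac in fct["factors"]:
        # leading (structurally supported) system only; the JSON report
        # keeps the full candidate list
        for bs in fac["block_systems"][:1]:
            blocks = " | ".join(",".join(b) for b in bs["blocks"])
            classes = ",".join(p["filter_class"]
                               for p in bs["block_profiles"])
            lines.append(f"- {fac['subgroup']} blocks [{blocks}] "
                         f"filters [{classes}]"
                         + (" block-circulant"
                            if bs.get("block_circulant") else ""))
    ideal = report["idealization"]
    lines.append("")
    lines.append(f"Idealization distance: {ideal['distance']} link units "
                 f"({100 * ideal['distance_fraction']:.1f}% of M).")
    return "\n".join(lines) + "\n"


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
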