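"""Fragment-library screening against reference panels.

Ranks candidate fragments by Tanimoto similarity to a panel of reference
molecules (e.g. Akt inhibitors, natural metabolites), selects dual-panel
sensitiser candidates that resemble members of *both* panels, calibrates the
fingerprint scheme against a set of pairs with known (printed) Tc values,
and renders CSV/JSON reports with maximum-common-substructure evidence.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chemstruct import (
    Molecule,
    SCHEMES,
    compute_descriptors,
    compute_fingerprint,
    ro3_filter,
    round_tc,
    tanimoto,
)
from .mcs import MatchRules, MCSResult, compute_mcs


@dataclass
class ReferencePanel:
    """A named, non-empty panel of reference molecules with unique names."""

    name: str
    members: list  # [(member name, Molecule), ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"panel {self.name!r} is empty")
        names = [n for n, _ in self.members]
        if len(set(names)) != len(names):
            raise ValueError(f"panel {self.name!r} has duplicate member names")


@dataclass
class ScreeningHit:
    """Per-fragment similarity record against one or two reference panels.

    ``per_reference_tc`` holds full-precision Tc values; reports render them
    at 2 decimals (half-up).  For dual-panel selections, ``panel_best`` maps
    each panel name to its (best reference, Tc) and ``panel_mcs`` carries MCS
    evidence against each panel's best reference.
    """

    fragment_id: str
    per_reference_tc: dict
    best_reference: str
    best_tc: float
    rank: int
    ro3_pass: bool
    mcs_vs_best: Optional[MCSResult] = None
    panel_best: dict = field(default_factory=dict)
    panel_mcs: dict = field(default_factory=dict)


def _best_reference(tc_map: dict) -> tuple[str, float]:
    # highest Tc; ties broken by reference name ascending for determinism
    best_tc = max(tc_map.values())
    name = min(n for n, v in tc_map.items() if v == best_tc)
    return name, best_tc


def rank_library(
    library: Sequence[Molecule],
    panel: ReferencePanel,
    scheme: str = "structural-keys-166",
    apply_ro3: bool = True,
    with_mcs: bool = False,
    mcs_rules: MatchRules = MatchRules(),
) -> list[ScreeningHit]:
    """Rank fragments by best Tc against the panel (stable total order).

    Sorted by best Tc descending, ties broken by fragment id ascending.
    With ``apply_ro3`` (default, mirroring a pre-filtered Ro3 fragment
    library) non-compliant fragments are dropped before ranking.
    """
    if not library:
        raise ValueError("empty fragment library")
    ref_fps = {name: compute_fingerprint(m, scheme) for name, m in panel.members}
    ref_mols = dict(panel.members)

    hits = []
    for frag in library:
        ro3_pass, _failed = ro3_filter(compute_descriptors(frag))
        if apply_ro3 and not ro3_pass:
            continue
        fp = compute_fingerprint(frag, scheme)
        tc_map = {name: tanimoto(fp, ref_fp) for name, ref_fp in ref_fps.items()}
        best_name, best_tc = _best_reference(tc_map)
        mcs_res = (
            compute_mcs(frag, ref_mols[best_name], rules=mcs_rules) if with_mcs else None
        )
        hits.append(
            ScreeningHit(
                fragment_id=frag.id,
                per_reference_tc=tc_map,
                best_reference=best_name,
                best_tc=best_tc,
                rank=0,
                ro3_pass=ro3_pass,
                mcs_vs_best=mcs_res,
            )
        )
    hits.sort(key=lambda h: (-h.best_tc, h.fragment_id))
    for position, hit in enumerate(hits, start=1):
        hit.rank = position
    return hits


def dual_panel_select(
    library: Sequence[Molecule],
    inhibitor_panel: ReferencePanel,
    metabolite_panel: ReferencePanel,
    scheme: str = "structural-keys-166",
    t_inhibitor: float = 0.5,
    t_metabolite: float = 0.5,
    apply_ro3: bool = True,
    with_mcs: bool = True,
    mcs_rules: MatchRules = MatchRules(),
) -> list[ScreeningHit]:
    """Select fragments similar to members of BOTH panels.

    A fragment qualifies when its best Tc against each panel meets that
    panel's threshold; qualifying hits are ranked by the *minimum* of the two
    best-Tc values, descending, and carry MCS evidence against both best
    references.
    """
    for t in (t_inhibitor, t_metabolite):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    by_panel = {}
    for panel, threshold in (
        (inhibitor_panel, t_inhibitor),
        (metabolite_panel, t_metabolite),
    ):
        ranked = rank_library(library, panel, scheme, apply_ro3=apply_ro3, with_mcs=False)
        by_panel[panel.name] = (
            {h.fragment_id: h for h in ranked},
            threshold,
            dict(panel.members),
        )

    selected = []
    first_panel = inhibitor_panel.name
    second_panel = metabolite_panel.name
    hits_a, thr_a, mols_a = by_panel[first_panel]
    hits_b, thr_b, mols_b = by_panel[second_panel]
    for frag in library:
        ha = hits_a.get(frag.id)
        hb = hits_b.get(frag.id)
        if ha is None or hb is None:
            continue
        if ha.best_tc < thr_a or hb.best_tc < thr_b:
            continue
        tc_map = dict(ha.per_reference_tc)
        tc_map.update(hb.per_reference_tc)
        best_name, best_tc = _best_reference(tc_map)
        hit = ScreeningHit(
            fragment_id=frag.id,
            per_reference_tc=tc_map,
            best_reference=best_name,
            best_tc=best_tc,
            rank=0,
            ro3_pass=ha.ro3_pass,
            panel_best={
                first_panel: (ha.best_reference, ha.best_tc),
                second_panel: (hb.best_reference, hb.best_tc),
            },
        )
        if with_mcs:
            hit.panel_mcs = {
                first_panel: compute_mcs(frag, mols_a[ha.best_reference], rules=mcs_rules),
                second_panel: compute_mcs(frag, mols_b[hb.best_reference], rules=mcs_rules),
            }
            hit.mcs_vs_best = hit.panel_mcs[
                first_panel if ha.best_tc >= hb.best_tc else second_panel
            ]
        selected.append(hit)

    selected.sort(
        key=lambda h: (-min(tc for _, tc in h.panel_best.values()), h.fragment_id)
    )
    for position, hit in enumerate(selected, start=1):
        hit.rank = position
    return selected


@dataclass(frozen=True)
class CalibrationResult:
    scheme: str
    max_abs_dev: float
    per_scheme_dev: dict


def calibrate_scheme(
    reference_pairs: Sequence[tuple],
    schemes: Optional[Sequence[str]] = None,
) -> CalibrationResult:
    """Select the fingerprint scheme best reproducing known Tc values.

    ``reference_pairs`` are ``(Molecule, Molecule, printed_tc)`` triples.
    Every candidate scheme is scored by its maximum absolute deviation from
    the printed values after 2-dp (half-up) rounding; the scheme with the
    smallest deviation wins, ties broken by scheme name.
    """
    if len(reference_pairs) < 2:
        raise ValueError("calibration needs at least two reference pairs")
    candidates = sorted(schemes) if schemes is not None else sorted(SCHEMES)
    per_scheme = {}
    for scheme in candidates:
        devs = []
        for mol_a, mol_b, printed in reference_pairs:
            tc = tanimoto(
                compute_fingerprint(mol_a, scheme), compute_fingerprint(mol_b, scheme)
            )
            devs.append(abs(round_tc(tc) - printed))
        per_scheme[scheme] = max(devs)
    best = min(per_scheme.items(), key=lambda kv: (kv[1], kv[0]))
    return CalibrationResult(scheme=best[0], max_abs_dev=best[1], per_scheme_dev=per_scheme)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _hit_row(hit: ScreeningHit, reference_names: list) -> dict:
    row = {
        "fragment_id": hit.fragment_id,
        "rank": hit.rank,
        "best_reference": hit.best_reference,
        "best_tc": round_tc(hit.best_tc),
        "ro3_pass": hit.ro3_pass,
    }
    for name in reference_names:
        tc = hit.per_reference_tc.get(name)
        row[f"tc_{name}"] = round_tc(tc) if tc is not None else ""
    mcs_res = hit.mcs_vs_best
    row["mcs_pattern"] = mcs_res.pattern if mcs_res else ""
    row["mcs_n_atoms"] = mcs_res.n_atoms if mcs_res else ""
    row["mcs_atoms_fragment"] = (
        ";".join(map(str, mcs_res.atoms_a())) if mcs_res else ""
    )
    row["mcs_atoms_reference"] = (
        ";".join(map(str, mcs_res.atoms_b())) if mcs_res else ""
    )
    return row


def make_report(hits: Sequence[ScreeningHit], format: str = "csv") -> str:
    """Render hits as CSV or JSON; the two carry identical reported values.

    The JSON rendering additionally retains full-precision Tc values and the
    per-panel MCS highlights as atom-index lists for each parent.
    """
    if not hits:
        raise ValueError("no hits to report")
    reference_names = sorted({n for h in hits for n in h.per_reference_tc})
    rows = [_hit_row(h, reference_names) for h in hits]
    if format == "csv":
        buf = io.StringIO()
        writer = csv.DictWriter(buf, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
        return buf.getvalue()
    if format == "json":
        payload = []
        for hit, row in zip(hits, rows):
            entry = dict(row)
            entry["per_reference_tc_full"] = dict(hit.per_reference_tc)
            entry["panel_best"] = {
                panel: {"reference": ref, "tc": tc, "tc_2dp": round_tc(tc)}
                for panel, (ref, tc) in hit.panel_best.items()
            }
            entry["panel_mcs"] = {
                panel: {
                    "pattern": res.pattern,
                    "n_atoms": res.n_atoms,
                    "n_bonds": res.n_bonds,
                    "atoms_fragment": list(res.atoms_a()),
                    "atoms_reference": list(res.atoms_b()),
                }
                for panel, res in hit.panel_mcs.items()
            }
            payload.append(entry)
        return json.dumps(payload, indent=2)
    raise ValueError(f"unknown report format {format!r}")
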