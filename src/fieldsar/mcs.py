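"""Common-graph pose similarity: connected MCS, in-place RMSD, match percents.

Docked poses of congeneric analogs share the receptor coordinate frame, so
pose similarity to a reference compound is measured WITHOUT superposition:
the maximum connected common subgraph (heavy atoms) between reference and
probe is found, and the RMSD is taken over the matched atom pairs in place.
Two coverage percentages accompany each RMSD:

    %RefMatch = 100 · |MCS| / heavy(reference)
    %MolMatch = 100 · |MCS| / heavy(probe)

so a small RMSD is only meaningful together with high coverage.

Atom compatibility requires equal element and aromaticity flag, and — by
default — membership in smallest rings of equal size; ``ring_relaxed`` keeps
the ring/chain distinction but ignores ring sizes, so e.g. a pyrrolidine can
match part of a piperidine.  Bonds match on equal order, aromatic with
aromatic.  Among all maximum-size mappings the one with the smallest
in-place RMSD is returned (poses share a frame, so this is well defined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .molecule import Molecule


@dataclass
class McsMapping:
    ref_id: str
    probe_id: str
    pairs: list[tuple[int, int]]  # (ref atom index, probe atom index)
    ring_relaxed: bool = False

    @property
    def size(self) -> int:
        return len(self.pairs)

    def __post_init__(self) -> None:
        refs = [i for i, _ in self.pairs]
        probes = [j for _, j in self.pairs]
        if len(set(refs)) != len(refs) or len(set(probes)) != len(probes):
            raise ValueError("MCS mapping must be injective on both sides")


@dataclass
class RmsdRecord:
    probe_id: str
    rmsd: float | None
    ref_match: int | None
    mol_match: int | None
    note: str = ""


class NoCommonGraphError(ValueError):
    pass


def _atoms_compatible(ref: Molecule, probe: Molecule, i: int, j: int,
                      ring_relaxed: bool) -> bool:
    a, b = ref.atoms[i], probe.atoms[j]
    if a.element != b.element or a.aromatic != b.aromatic:
        return False
    ri, rj = ref.in_ring(i), probe.in_ring(j)
    if ri != rj:
        return False
    if ri and not ring_relaxed and not (set(ref.ring_sizes(i)) & set(probe.ring_sizes(j))):
        return False
    return True


def _bonds_compatible(o1: float, o2: float) -> bool:
    return o1 == o2  # aromatic encoded as a distinct order, so this covers it


def find_common_graph(ref: Molecule, probe: Molecule, ring_relaxed: bool = False,
                      max_steps: int = 2_000_000) -> McsMapping:
    """Maximum connected common subgraph over heavy atoms (exhaustive,
    branch-and-bound, deterministic atom ordering, bounded by ``max_steps``)."""
    ref_heavy = ref.heavy_indices
    probe_heavy = probe.heavy_indices
    if not ref_heavy or not probe_heavy:
        raise NoCommonGraphError("both molecules need at least one heavy atom")

    compat = {
        i: [j for j in probe_heavy if _atoms_compatible(ref, probe, i, j, ring_relaxed)]
        for i in ref_heavy
    }
    ref_adj = {i: [n for n in ref.neighbors(i) if ref.atoms[n].element != "H"]
               for i in ref_heavy}
    rc = ref.coords
    pc = probe.coords

    best: dict = {"size": 0, "ssd": np.inf, "pairs": []}
    budget = [max_steps]
    seen: set[frozenset] = set()

    def consider(mapping: dict[int, int]) -> None:
        size = len(mapping)
        if size == 0 or size < best["size"]:
            return
        ssd = sum(float(np.sum((rc[i] - pc[j]) ** 2)) for i, j in mapping.items())
        if size > best["size"] or ssd < best["ssd"] - 1e-12:
            best.update(size=size, ssd=ssd, pairs=sorted(mapping.items()))

    def extend(mapping: dict[int, int], used_probe: set[int], i0: int) -> None:
        if budget[0] <= 0:
            return
        budget[0] -= 1
        key = frozenset(mapping.items())
        if key in seen:
            return
        seen.add(key)
        consider(mapping)
        # frontier: unmapped ref atoms (index ≥ seed) bonded to a mapped atom
        candidates: list[tuple[int, int]] = []
        for i in sorted(mapping):
            for i2 in ref_adj[i]:
                if i2 in mapping or i2 < i0:
                    continue
                o_ref = ref.bond_order(i, i2)
                for j2 in compat[i2]:
                    if j2 in used_probe:
                        continue
                    o_probe = probe.bond_order(mapping[i], j2)
                    if o_probe is None or not _bonds_compatible(o_ref, o_probe):
                        continue
                    if (i2, j2) not in candidates:
                        candidates.append((i2, j2))
        # bound: even mapping every remaining compatible ref atom cannot beat best
        upper = len(mapping) + sum(
            1 for i in ref_heavy if i not in mapping and i >= i0 and compat[i]
        )
        if upper < best["size"]:
            return
        for i2, j2 in sorted(candidates):
            mapping[i2] = j2
            used_probe.add(j2)
            extend(mapping, used_probe, i0)
            del mapping[i2]
            used_probe.discard(j2)

    for i0 in ref_heavy:  # each fragment found from its minimal ref atom
        for j0 in compat[i0]:
            if best["size"] >= len([i for i in ref_heavy if i >= i0]):
                break
            extend({i0: j0}, {j0}, i0)

    if best["size"] == 0:
        raise NoCommonGraphError(
            f"no common atom between {ref.id} and {probe.id}")
    return McsMapping(ref.id, probe.id, best["pairs"], ring_relaxed)


def rmsd_in_place(mapping: McsMapping, ref: Molecule, probe: Molecule) -> float:
    """RMSD over the matched pairs with NO superposition (shared frame)."""
    if mapping.size == 0:
        raise ValueError("empty mapping")
    rc, pc = ref.coords, probe.coords
    n_ref, n_probe = len(ref.atoms), len(probe.atoms)
    for i, j in mapping.pairs:
        if not (0 <= i < n_ref and 0 <= j < n_probe):
            raise IndexError(f"mapping pair ({i},{j}) out of range")
    d2 = [float(np.sum((rc[i] - pc[j]) ** 2)) for i, j in mapping.pairs]
    return float(np.sqrt(np.mean(d2)))


def match_percents(mapping: McsMapping, ref: Molecule, probe: Molecule) -> tuple[int, int]:
    """(%RefMatch, %MolMatch) rounded to the nearest integer."""
    if mapping.size == 0:
        raise ValueError("empty mapping")
    hr, hp = ref.heavy_atom_count, probe.heavy_atom_count
    if hr == 0 or hp == 0:
        raise ValueError("zero heavy atoms")
    return (round(100.0 * mapping.size / hr), round(100.0 * mapping.size / hp))


def rmsd_table(ref: Molecule, probes: list[Molecule],
               ring_relaxed: bool = False) -> pd.DataFrame:
    """One row per probe: id, rmsd_A, ref_match_pct, mol_match_pct, note."""
    records: list[RmsdRecord] = []
    for probe in probes:
        try:
            m = find_common_graph(ref, probe, ring_relaxed=ring_relaxed)
            r = rmsd_in_place(m, ref, probe)
            pr, pm = match_percents(m, ref, probe)
            records.append(RmsdRecord(probe.id, round(r, 2), pr, pm))
        except NoCommonGraphError:
            records.append(RmsdRecord(probe.id, None, None, None, "no common graph"))
    return pd.DataFrame(
        [{"id": r.probe_id, "rmsd_A": r.rmsd, "ref_match_pct": r.ref_match,
          "mol_match_pct": r.mol_match, "note": r.note} for r in records]
    )
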