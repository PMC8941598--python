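"""MS2 spectra: container, MGF IO, and the fragment-similarity score.

The similarity score blends fragment sharing and intensity agreement:
``score = w_f * F + (1 - w_f) * C`` with ``F = 2 * n_matched / (n_a + n_b)``
(a Dice coefficient over fragments, matched greedily closest-first within a
m/z tolerance) and ``C`` the cosine similarity of the two intensity vectors
over the union of fragments (zero for unmatched peaks). The score is symmetric,
lies in [0, 1], equals 1 exactly for identical spectra and 0 for disjoint ones,
and is invariant to uniform intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf


@dataclass
class MS2Spectrum:
    """Precursor plus fragment peak list, base peak normalized to 100."""

    precursor_mz: float
    peaks: list[tuple[float, float]]  # (fragment m/z, relative intensity (0, 100])
    source: str = "sample"  # sample | standard | simulated
    name: str = ""

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p[0])
        for mz, inten in self.peaks:
            if inten <= 0:
                raise ValueError(f"nonpositive fragment intensity at m/z {mz}")

    @classmethod
    def from_raw(cls, precursor_mz, mzs, intensities, source="sample", name="") -> "MS2Spectrum":
        """Build from raw arrays, normalizing the base peak to 100."""
        mzs = np.asarray(mzs, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        keep = intensities > 0
        mzs, intensities = mzs[keep], intensities[keep]
        if mzs.size == 0:
            raise ValueError("spectrum has no peaks with positive intensity")
        intensities = 100.0 * intensities / intensities.max()
        return cls(precursor_mz, list(zip(mzs.tolist(), intensities.tolist())), source, name)

    @property
    def mzs(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def greedy_fragment_match(
    a: MS2Spectrum, b: MS2Spectrum, frag_tol: float = 0.01
) -> list[tuple[int, int]]:
    """Pair fragments of `a` and `b` within `frag_tol` Da, closest pairs first,
    each fragment used at most once. Deterministic and symmetric."""
    mza, mzb = a.mzs, b.mzs
    pairs = []
    for i, ma in enumerate(mza):
        for j, mb in enumerate(mzb):
            d = abs(ma - mb)
            if d <= frag_tol:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    return matched


def ms2_similarity(
    a: MS2Spectrum, b: MS2Spectrum, frag_tol: float = 0.01, fragment_weight: float = 0.5
) -> float:
    """Similarity in [0, 1]: 0 = no shared fragments, 1 = identical spectra."""
    if not a.peaks or not b.peaks:
        raise ValueError("cannot score an empty spectrum")
    matched = greedy_fragment_match(a, b, frag_tol)
    na, nb = len(a.peaks), len(b.peaks)
    f_share = 2.0 * len(matched) / (na + nb)

    ia, ib = a.intensities, b.intensities
    # union vectors: matched pairs aligned, unmatched peaks paired with zero
    va, vb = [], []
    in_a = {i for i, _ in matched}
    in_b = {j for _, j in matched}
    for i, j in matched:
        va.append(ia[i])
        vb.append(ib[j])
    for i in range(na):
        if i not in in_a:
            va.append(ia[i])
            vb.append(0.0)
    for j in range(nb):
        if j not in in_b:
            va.append(0.0)
            vb.append(ib[j])
    va = np.asarray(va)
    vb = np.asarray(vb)
    cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
    cos = min(max(cos, 0.0), 1.0)
    return fragment_weight * f_share + (1.0 - fragment_weight) * cos


# ---------------------------------------------------------------------------
# MGF IO (pyteomics-backed)

def write_mgf(spectra: list[MS2Spectrum], path: str | Path) -> None:
    entries = []
    for k, sp in enumerate(spectra):
        entries.append(
            {
                "m/z array": sp.mzs,
                "intensity array": sp.intensities,
                "params": {
                    "title": sp.name or f"spectrum_{k}",
                    "pepmass": sp.precursor_mz,
                    "charge": "1+",
                    "source": sp.source,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[MS2Spectrum]:
    out = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            pep = params.get("pepmass", (0.0,))
            precursor = pep[0] if isinstance(pep, (tuple, list)) else float(pep)
            out.append(
                MS2Spectrum.from_raw(
                    precursor,
                    entry["m/z array"],
                    entry["intensity array"],
                    source=str(params.get("source", "sample")),
                    name=str(params.get("title", "")),
                )
            )
    return out
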