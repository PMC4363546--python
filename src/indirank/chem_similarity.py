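"""Fingerprints and pairwise Tanimoto similarity.

Supported fingerprint families:

* ``ECFP`` — extended-connectivity (Morgan) circular fingerprints with
  standard atom invariants; diameter d means radius d/2.
* ``FCFP`` — same topology with functional-class atom invariants.
* ``MACCS`` — the fixed 166 structural keys.
* ``PATH`` — a hashed linear-path fingerprint over fragments up to 7 bonds,
  an approximation of Open Babel's FP2 family.  It is documented as such and
  excluded from default benchmarks.

Circular and path fingerprints are folded to 2048 bits by default; folding
length is a free parameter the similarity ranking is mildly sensitive to.
Fingerprints are represented as numpy uint8 arrays of 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .dataio import Dataset

__all__ = [
    "FingerprintSpec",
    "SimilarityProvider",
    "fingerprint",
    "tanimoto",
    "similarity_matrix",
    "largest_fragment",
    "load_similarity_table",
    "write_similarity_table",
]

FAMILIES = ("ECFP", "FCFP", "MACCS", "PATH")


@dataclass(frozen=True)
class FingerprintSpec:
    """Which fingerprint to compute.

    ``diameter`` (2, 4 or 6) applies only to the circular families and is
    twice the Morgan radius, matching the ECFP_d / FCFP_d naming convention.
    """

    family: str = "ECFP"
    diameter: int | None = 4
    folded_length: int = 2048

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown fingerprint family {self.family!r}")
        circular = self.family in ("ECFP", "FCFP")
        if circular:
            if self.diameter not in (2, 4, 6):
                raise ValueError("circular fingerprints need diameter in {2, 4, 6}")
        elif self.diameter is not None:
            raise ValueError(f"{self.family} takes no diameter")
        if self.family == "MACCS" and self.folded_length != 166:
            object.__setattr__(self, "folded_length", 166)

    @classmethod
    def parse(cls, name: str, folded_length: int = 2048) -> "FingerprintSpec":
        """Parse names like ``ECFP_4``, ``FCFP_2``, ``MACCS``, ``PATH``."""
        name = name.upper()
        if "_" in name:
            fam, d = name.split("_", 1)
            return cls(fam, int(d), folded_length)
        if name == "MACCS":
            return cls("MACCS", None, 166)
        return cls(name, None, folded_length)

    def __str__(self) -> str:
        return f"{self.family}_{self.diameter}" if self.diameter else self.family


def _generator(spec: FingerprintSpec):
    if spec.family == "ECFP":
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=spec.diameter // 2, fpSize=spec.folded_length
        )
    if spec.family == "FCFP":
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=spec.diameter // 2,
            fpSize=spec.folded_length,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
    if spec.family == "PATH":
        return rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=7, fpSize=spec.folded_length
        )
    return None  # MACCS handled separately


def largest_fragment(smiles: str) -> str:
    """Keep only the largest covalent fragment (crude salt stripping).

    Optional preprocessing, off by default everywhere.
    """
    frags = smiles.split(".")
    return max(frags, key=len) if len(frags) > 1 else smiles


def fingerprint(smiles: str, spec: FingerprintSpec) -> np.ndarray:
    """Compute the bit vector for one molecule.

    Deterministic in (smiles, spec); SMILES variants of the same molecule
    yield identical vectors because RDKit perceives the molecular graph
    before enumerating environments.  Unparseable SMILES is an error.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if spec.family == "MACCS":
        keys = MACCSkeys.GenMACCSKeys(mol)  # 167 bits; bit 0 is always unset
        arr = np.zeros(166, dtype=np.uint8)
        for b in keys.GetOnBits():
            if b >= 1:
                arr[b - 1] = 1
        return arr
    fp = _generator(spec).GetFingerprint(mol)
    arr = np.zeros(spec.folded_length, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a∧b| / |a∨b| of two equal-length bit vectors.

    Two all-zero vectors have similarity 0 by convention.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(a & b)) / union


class SimilarityProvider:
    """Pairwise similarity function w^s over a set of drugs.

    Backed either by a fingerprint dictionary (similarities computed
    lazily and cached) or by a precomputed table.  Drugs outside the
    support — including drugs whose SMILES failed to parse, listed in
    ``skipped`` — report similarity 0 to everything.  Self-similarity is 1
    for supported drugs.
    """

    def __init__(
        self,
        fingerprints: Mapping[str, np.ndarray] | None = None,
        table: Mapping[tuple[str, str], float] | None = None,
        skipped: Iterable[str] = (),
    ):
        self._fps = dict(fingerprints) if fingerprints else {}
        self._table: dict[tuple[str, str], float] = {}
        if table:
            for (a, b), s in table.items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"similarity out of range for ({a!r}, {b!r}): {s}")
                self._table[(a, b) if a <= b else (b, a)] = float(s)
        self.skipped: frozenset[str] = frozenset(skipped)

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self._fps) | frozenset(x for k in self._table for x in k)

    def get(self, a: str, b: str) -> float:
        if a in self.skipped or b in self.skipped:
            return 0.0
        if a == b:
            return 1.0 if (a in self._fps or any(a in k for k in self._table)) else 0.0
        key = (a, b) if a <= b else (b, a)
        if key in self._table:
            return self._table[key]
        if a in self._fps and b in self._fps:
            s = tanimoto(self._fps[a], self._fps[b])
            self._table[key] = s
            return s
        return 0.0

    __call__ = get


def similarity_matrix(
    dataset: Dataset,
    spec: FingerprintSpec = FingerprintSpec(),
    strip_salts: bool = False,
) -> SimilarityProvider:
    """Fingerprint every drug in *dataset* and return a similarity provider.

    Drugs whose SMILES cannot be parsed are collected in the provider's
    ``skipped`` set and report 0 similarity to everything rather than
    aborting the run.
    """
    fps: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for d in dataset:
        smi = largest_fragment(d.smiles) if strip_salts else d.smiles
        try:
            fps[d.drug_id] = fingerprint(smi, spec)
        except ValueError:
            skipped.append(d.drug_id)
    return SimilarityProvider(fingerprints=fps, skipped=skipped)


def load_similarity_table(path: str | Path) -> SimilarityProvider:
    """Load a cached pairwise-similarity TSV (drug_id_a, drug_id_b, similarity).

    Only one triangle need be present; the provider is symmetric either way.
    """
    table: dict[tuple[str, str], float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {n: header.index(n) for n in ("drug_id_a", "drug_id_b", "similarity")}
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            a, b = f[col["drug_id_a"]], f[col["drug_id_b"]]
            if a != b:
                table[(a, b) if a <= b else (b, a)] = float(f[col["similarity"]])
    return SimilarityProvider(table=table)


def write_similarity_table(
    provider: SimilarityProvider, drug_ids: list[str], path: str | Path
) -> None:
    """Write the upper triangle of pairwise similarities over *drug_ids*."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id_a\tdrug_id_b\tsimilarity\n")
        for i, a in enumerate(drug_ids):
            for b in drug_ids[i + 1 :]:
                fh.write(f"{a}\t{b}\t{provider.get(a, b):.6g}\n")
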