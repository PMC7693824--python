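"""Synthetic precursor cDNAs with ground truth.

Generates prepro-peptide cDNAs that follow the family architecture —
21-residue signal peptide ending in its single Cys, a D/E-rich spacer of
19-22 residues ending in Lys-Arg, and a mature peptide sampled from the
family's positional residue frequencies — together with the exact
segmentation, so the parser can be tested without any external sequence.

Uniqueness constraints (one Cys in the signal window, one K-R site) make
the default fixtures provably unambiguous; ``adversarial=True`` plants
decoy K-R dipeptides that exercise the last-eligible-site rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .compare import conservation_profile
from .datasets import family_members
from .physchem import net_charge_formal
from .precursor import translate_cds

_MAX_ATTEMPTS = 1000

#: Charge envelope the family occupies; sampled matures are kept inside it.
CHARGE_ENVELOPE = (-1, 4)

_HYDROPHOBIC_POOL = "AVLIFMW"
_NEUTRAL_POOL = "GSTNQHPY"


@dataclass(frozen=True)
class SyntheticTruth:
    record_id: str
    cdna: str
    protein: str
    signal: str
    acidic: str
    mature: str
    amidated: bool
    seed: int


@lru_cache(maxsize=1)
def _family_profile() -> tuple[tuple[dict[str, float], ...], dict[str, float]]:
    """Left-flush positional frequencies plus overall residue frequencies."""
    seqs = [r.sequence for r in family_members()]
    profile = conservation_profile(seqs, mode="left_flush")
    overall: dict[str, float] = {}
    total = sum(len(s) for s in seqs)
    for s in seqs:
        for a in s:
            overall[a] = overall.get(a, 0.0) + 1.0 / total
    return profile.columns, overall


def _draw(rng: np.random.Generator, weights: dict[str, float]) -> str:
    residues = sorted(weights)
    p = np.array([weights[a] for a in residues])
    return residues[rng.choice(len(residues), p=p / p.sum())]


def _sample_signal(rng: np.random.Generator, signal_len: int) -> str:
    # M + hydrophobic-biased core + the terminal Cys; no other Cys or the
    # first-Cys rule would fire early.
    weights = {a: 4.0 for a in _HYDROPHOBIC_POOL}
    weights.update({a: 1.0 for a in _NEUTRAL_POOL})
    core = "".join(_draw(rng, weights) for _ in range(signal_len - 2))
    return "M" + core + "C"


def _sample_acidic(
    rng: np.random.Generator, length: int, adversarial: bool
) -> str:
    weights = {"D": 6.0, "E": 6.0}
    weights.update({a: 1.0 for a in "GSTANQ"})
    weights["K"] = 0.8
    for _ in range(_MAX_ATTEMPTS):
        body = "".join(_draw(rng, weights) for _ in range(length - 2))
        if adversarial and length >= 8:
            # plant an earlier, decoy K-R site inside the spacer
            pos = int(rng.integers(1, length - 4))
            body = body[:pos] + "KR" + body[pos + 2:]
        acidic = body + "KR"
        de_fraction = sum(a in "DE" for a in acidic) / len(acidic)
        n_kr = acidic.count("KR")
        if de_fraction >= 0.4 and n_kr == (2 if adversarial else 1):
            return acidic
    raise RuntimeError("could not satisfy acidic-spacer constraints")


def _sample_mature(
    rng: np.random.Generator, length: int, amidated: bool, adversarial: bool
) -> str:
    columns, overall = _family_profile()
    for _ in range(_MAX_ATTEMPTS):
        residues = []
        for i in range(length):
            weights = dict(columns[i]) if i < len(columns) else dict(overall)
            residues.append(_draw(rng, weights))
        mature = "".join(residues)
        if adversarial and length >= MIN_DECOY_LEN:
            # decoy K-R too close to the C-terminus to be an eligible site
            pos = length - int(rng.integers(4, 12))
            mature = mature[:pos] + "KR" + mature[pos + 2:]
            kr_ok = True
        else:
            kr_ok = "KR" not in mature
        if (
            kr_ok
            and "C" not in mature
            and not mature.endswith("G")
            and CHARGE_ENVELOPE[0]
            <= net_charge_formal(mature, amidated)
            <= CHARGE_ENVELOPE[1]
        ):
            return mature
    raise RuntimeError("could not satisfy mature-peptide constraints")


MIN_DECOY_LEN = 16

_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in unambiguous_dna_by_id[1].forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for codons in _BACK_TABLE.values():
    codons.sort()
_STOPS = sorted(unambiguous_dna_by_id[1].stop_codons)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _BACK_TABLE[a][rng.integers(len(_BACK_TABLE[a]))] for a in protein
    )


def generate_precursor(
    seed: int,
    signal_len: int = 21,
    acidic_len: tuple[int, int] = (19, 22),
    mature_len: tuple[int, int] = (21, 32),
    amidation_prob: float = 0.9,
    adversarial: bool = False,
    record_id: Optional[str] = None,
) -> SyntheticTruth:
    """One synthetic precursor with its exact segmentation.

    Deterministic for a given seed and parameter set.
    """
    if not 15 <= signal_len <= 25:
        raise ValueError("signal_len outside the parseable window")
    rng = np.random.default_rng(seed)
    signal = _sample_signal(rng, signal_len)
    acidic = _sample_acidic(
        rng, int(rng.integers(acidic_len[0], acidic_len[1] + 1)), adversarial
    )
    amidated = bool(rng.random() < amidation_prob)
    mature = _sample_mature(
        rng, int(rng.integers(mature_len[0], mature_len[1] + 1)),
        amidated, adversarial,
    )
    mature_raw = mature + "G" if amidated else mature
    protein = signal + acidic + mature_raw
    for _ in range(_MAX_ATTEMPTS):
        utr5 = "".join(
            "CGT"[rng.integers(3)] for _ in range(rng.integers(0, 31))
        )
        utr3 = "".join(
            "ACGT"[rng.integers(4)] for _ in range(rng.integers(0, 31))
        )
        cdna = (
            utr5
            + _back_translate(rng, protein)
            + _STOPS[rng.integers(len(_STOPS))]
            + utr3
            + "A" * 16
        )
        # Reject the rare codon randomization whose off-frame reading yields
        # a longer spurious ORF; fixtures must be unambiguous by design.
        if translate_cds(cdna, "auto") == protein:
            break
    else:
        raise RuntimeError("could not build an unambiguous cDNA")
    return SyntheticTruth(
        record_id=record_id or f"synt-{seed}",
        cdna=cdna,
        protein=protein,
        signal=signal,
        acidic=acidic,
        mature=mature,
        amidated=amidated,
        seed=seed,
    )


def generate_batch(
    n: int, seed: int, **params
) -> list[SyntheticTruth]:
    """``n`` independent records; record i is driven by sub-seed (seed, i)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for i in range(n):
        sub = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        out.append(
            generate_precursor(sub, record_id=f"synt-{i + 1:04d}", **params)
        )
    return out


def emit_fixtures(
    n: int, seed: int, out_dir, **params
) -> tuple[Path, Path]:
    """Write ``fixtures.fasta`` and ``truth.json``; byte-stable per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_batch(n, seed, **params)
    fasta = out_dir / "fixtures.fasta"
    truth = out_dir / "truth.json"
    with open(fasta, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.record_id}\n{rec.cdna}\n")
    payload = [dataclasses.asdict(rec) for rec in records]
    with open(truth, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return fasta, truth
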