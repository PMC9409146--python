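"""Seeded synthetic inputs with ground-truth manifests.

Generators for every input the pipeline consumes: annotated transcriptomes
with ORFs planted at known coordinates, canonical proteomes carrying decoy
homologs for a chosen subset of plantings, and pooled case/control PSM
cohorts with planted case-exclusive, fold-change, detection-odds-ratio and
null cryptoproteins. Everything is driven by a single integer seed through
``numpy.random.default_rng`` and is byte-identical across runs for the
same seed.

Planted ORFs are constructed so that enumeration recovers them exactly
under the default 5'-most-AUG convention: an in-frame stop codon is placed
immediately upstream of the planted AUG, and the planted coding region
contains no internal in-frame stop. Cohort PSM counts are drawn from a
negative binomial (spectral counts are overdispersed), with case/control
mean ratios equal to the planted effect and structural zeros in controls
for case-exclusive plantings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology_purge import fold_il, tryptic_peptides
from .orf_enumerator import _CODON_TABLE, CryptoDbEntry
from .transcript_io import CohortDesign, PsmRecord, TranscriptRecord

logger = logging.getLogger(__name__)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")

# aa -> synonymous codons, derived from the standard table
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    if _aa != "*":
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class PlantedOrfSpec:
    """Specification of one ORF to plant in a synthetic transcriptome."""

    name: str
    biotype: str = "lincRNA"
    codon_count: int = 60
    should_survive_purge: bool = True


@dataclass(frozen=True)
class PlantedOrf:
    """A planted ORF as realized in the generated transcriptome."""

    name: str
    transcript_id: str
    frame: int
    nt_start: int
    nt_end: int
    aa_sequence: str
    biotype: str
    should_survive_purge: bool


@dataclass
class TruthManifest:
    """Ground truth of a synthetic dataset.

    ``effects`` maps orf_id -> (kind, value) with kind in
    {case_exclusive, fold_change, odds_ratio, null}; value is the planted
    fold change or detection odds ratio (1.0 for the others).
    """

    planted_orfs: list[PlantedOrf] = field(default_factory=list)
    effects: dict[str, tuple[str, float]] = field(default_factory=dict)
    params: dict[str, str] = field(default_factory=dict)
    seed: int = 0


_EFFECT_KINDS = ("case_exclusive", "fold_change", "odds_ratio", "null")


def write_truth_manifest(manifest: TruthManifest, path: str | Path) -> None:
    """Write a manifest as a flat TSV (round-trips through the reader)."""
    rows: list[dict] = [{"record_type": "seed", "key": "seed", "value": str(manifest.seed)}]
    rows += [{"record_type": "param", "key": k, "value": v} for k, v in sorted(manifest.params.items())]
    for o in manifest.planted_orfs:
        rows.append(
            {
                "record_type": "planted_orf",
                "key": o.name,
                "value": "|".join(
                    [o.transcript_id, str(o.frame), str(o.nt_start), str(o.nt_end),
                     o.aa_sequence, o.biotype, str(int(o.should_survive_purge))]
                ),
            }
        )
    for orf_id, (kind, value) in sorted(manifest.effects.items()):
        rows.append({"record_type": "effect", "key": orf_id, "value": f"{kind}|{value!r}"})
    try:
        pd.DataFrame(rows, columns=["record_type", "key", "value"]).to_csv(path, sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed to write manifest to {path}: {exc}") from exc


def read_truth_manifest(path: str | Path) -> TruthManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    m = TruthManifest()
    for row in df.to_dict("records"):
        rt = row["record_type"]
        if rt == "seed":
            m.seed = int(row["value"])
        elif rt == "param":
            m.params[row["key"]] = row["value"]
        elif rt == "planted_orf":
            tid, frame, s, e, aa, bt, surv = row["value"].split("|")
            m.planted_orfs.append(
                PlantedOrf(row["key"], tid, int(frame), int(s), int(e), aa, bt, bool(int(surv)))
            )
        elif rt == "effect":
            kind, value = row["value"].split("|")
            if kind not in _EFFECT_KINDS:
                raise ValueError(f"unknown effect kind {kind!r} in {path}")
            m.effects[row["key"]] = (kind, float(value))
        else:
            raise ValueError(f"unknown record_type {rt!r} in {path}")
    return m


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_AA20), size=n))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_NT), size=n))


def _encode_orf(rng: np.random.Generator, aa: str) -> str:
    """Back-translate with a random synonymous codon per residue, plus a stop."""
    codons = [_AA_TO_CODONS[a][rng.integers(0, len(_AA_TO_CODONS[a]))] for a in aa]
    codons.append(_STOPS[rng.integers(0, 3)])
    return "".join(codons)


def _planted_aa(rng: np.random.Generator, codon_count: int, min_tryptic: int = 8) -> str:
    """Random protein of the given length guaranteed to yield a tryptic
    peptide of length >= min_tryptic (so the purge can see it)."""
    for _ in range(100):
        aa = "M" + _random_aa(rng, codon_count - 1)
        if any(len(p) >= min_tryptic for p in tryptic_peptides(aa, min_tryptic)):
            return aa
    raise RuntimeError("could not generate a plantable protein")  # pragma: no cover


def simulate_transcriptome(
    n_transcripts: int,
    biotype_mix: Mapping[str, float] | None = None,
    planted_orf_specs: Sequence[PlantedOrfSpec] = (),
    seed: int = 0,
    n_proteins: int = 200,
    pad_codons: int = 20,
) -> tuple[list[TranscriptRecord], list[tuple[str, str]], TruthManifest]:
    """Generate a transcriptome, a canonical proteome, and the truth manifest.

    ``n_transcripts`` background transcripts (random sequence, biotypes drawn
    from ``biotype_mix``) are generated alongside one transcript per planted
    spec. Planted ORFs sit behind an in-frame upstream stop so enumeration
    recovers them at their recorded coordinates. The proteome consists of
    ``n_proteins`` random proteins; for every planting with
    ``should_survive_purge=False`` one of its long tryptic peptides is
    embedded in a random protein (an exact decoy homolog), while plantings
    meant to survive are verified to share no tryptic 8-mer (I/L folded)
    with the proteome.
    """
    if biotype_mix is None:
        biotype_mix = {"lincRNA": 0.4, "processed_transcript": 0.3, "retained_intron": 0.3}
    rng = np.random.default_rng(seed)
    manifest = TruthManifest(seed=seed, params={
        "n_transcripts": str(n_transcripts),
        "n_proteins": str(n_proteins),
        "n_planted": str(len(planted_orf_specs)),
    })
    transcripts: list[TranscriptRecord] = []

    for i, spec in enumerate(planted_orf_specs):
        if spec.codon_count < 2:
            raise ValueError(f"planted spec {spec.name!r} unsatisfiable: codon_count < 2")
        aa = _planted_aa(rng, spec.codon_count)
        orf_nt = _encode_orf(rng, aa)
        frame = int(rng.integers(0, 3))
        upstream_len = frame + 3 * int(rng.integers(1, pad_codons + 1))
        upstream = _random_nt(rng, upstream_len - 3) + _STOPS[rng.integers(0, 3)]
        downstream = _random_nt(rng, int(rng.integers(3, 3 * pad_codons + 1)))
        seq = upstream + orf_nt + downstream
        tid = f"SYNT{i:05d}.1"
        transcripts.append(TranscriptRecord(tid, f"SYNG{i:05d}.1", f"GENE{i}", spec.biotype, seq))
        manifest.planted_orfs.append(
            PlantedOrf(
                name=spec.name,
                transcript_id=tid,
                frame=frame,
                nt_start=upstream_len,
                nt_end=upstream_len + len(orf_nt),
                aa_sequence=aa,
                biotype=spec.biotype,
                should_survive_purge=spec.should_survive_purge,
            )
        )

    biotypes = list(biotype_mix)
    probs = np.array([biotype_mix[b] for b in biotypes], dtype=float)
    probs = probs / probs.sum()
    for i in range(n_transcripts):
        bt = biotypes[rng.choice(len(biotypes), p=probs)]
        seq = _random_nt(rng, int(rng.integers(120, 600)))
        tid = f"BGT{i:05d}.1"
        transcripts.append(TranscriptRecord(tid, f"BGG{i:05d}.1", f"BG{i}", bt, seq))

    proteome = [(f"CANON{j:04d}", _random_aa(rng, int(rng.integers(200, 401)))) for j in range(n_proteins)]
    for o in manifest.planted_orfs:
        if o.should_survive_purge:
            continue
        peps = sorted(tryptic_peptides(o.aa_sequence, 8), key=lambda p: (-len(p), p))
        pep = peps[0]
        # append rather than insert: a mid-sequence insertion could split a
        # peptide planted earlier in the same protein
        j = int(rng.integers(0, n_proteins))
        acc, seq = proteome[j]
        proteome[j] = (acc, seq + pep)

    text = "|".join(fold_il(seq) for _, seq in proteome)
    for o in manifest.planted_orfs:
        if o.should_survive_purge:
            shared = [p for p in tryptic_peptides(fold_il(o.aa_sequence), 8) if p in text]
            if shared:  # pragma: no cover - astronomically unlikely for random sequence
                raise RuntimeError(
                    f"planted survivor {o.name} accidentally shares peptides {shared} with the proteome"
                )
    return transcripts, proteome, manifest


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass(frozen=True)
class NoiseSpec:
    """Per-sample PSM depth and contamination of a simulated cohort.

    mean_count : negative-binomial mean spectral count per detected
        cryptoprotein per pool (baseline group).
    nb_dispersion : NB size parameter; variance = mean + mean^2/size.
    q_signal_max : planted-signal q-values are U(0, q_signal_max).
    decoy_fdr_frac : extra PSMs, per signal PSM, carrying q above the FDR
        threshold (exercises the FDR filter).
    canonical_frac : extra PSMs whose peptide is a canonical substring
        (exercises the first pass).
    unmatched_frac : extra PSMs matching neither database.
    detect_prob_control : control-group detection probability used by
        ``odds_ratio`` effects.
    """

    mean_count: float = 8.0
    nb_dispersion: float = 5.0
    q_signal_max: float = 0.09
    decoy_fdr_frac: float = 0.05
    canonical_frac: float = 0.10
    unmatched_frac: float = 0.02
    detect_prob_control: float = 0.4


def make_design(
    n_case_pools: int,
    n_control_pools: int,
    cohort: str = "newly_diagnosed",
    matched: bool = False,
    seed: int = 0,
) -> list[CohortDesign]:
    """A pooled case/control design with realistic pool sizes.

    Newly diagnosed cases are pools of 3 patients; pre-diagnostic case
    pools hold 4-14 patients; control pools hold 8-30 individuals.
    ``matched=True`` pairs case pool i with control pool i in stratum
    ``S{i}`` (requires equal pool counts).
    """
    rng = np.random.default_rng(seed)
    if matched and n_case_pools != n_control_pools:
        raise ValueError("matched design requires equal case and control pool counts")
    design = []
    for i in range(n_case_pools):
        size = 3 if cohort == "newly_diagnosed" else int(rng.integers(4, 15))
        design.append(
            CohortDesign(f"case_{i:02d}", "case", size, f"S{i}" if matched else None, cohort)
        )
    for i in range(n_control_pools):
        design.append(
            CohortDesign(
                f"control_{i:02d}", "control", int(rng.integers(8, 31)),
                f"S{i}" if matched else None, cohort,
            )
        )
    return design


def _nb_draw(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def _group_mean(kind: str, value: float, group: str, noise: NoiseSpec) -> float:
    base = noise.mean_count
    if kind == "null":
        return base
    if kind == "fold_change":
        return base * value if group == "case" else base
    if kind == "case_exclusive":
        return base if group == "case" else 0.0
    raise ValueError(f"unknown effect kind {kind!r}")


def simulate_psm_cohort(
    cryptodb: Sequence[CryptoDbEntry],
    design: Sequence[CohortDesign],
    effect_spec: Mapping[str, tuple[str, float]],
    noise: NoiseSpec | None = None,
    seed: int = 0,
    proteome: Sequence[tuple[str, str]] = (),
) -> tuple[list[PsmRecord], TruthManifest]:
    """Simulate a pooled case/control PSM cohort over a cryptoDB.

    ``effect_spec`` maps orf_id -> (kind, value): ``case_exclusive``
    (structural zero control counts), ``fold_change`` (case mean = value x
    control mean), ``odds_ratio`` (detection-probability contrast with the
    given odds ratio; counts zero-truncated NB when detected) or ``null``.
    Signal q-values pass the FDR filter; decoy PSMs above the threshold,
    canonical-peptide PSMs and unmatched PSMs are added per ``noise`` to
    exercise every filter. Peptides are drawn from each entry's tryptic
    peptides that are unique within the database and absent from the
    canonical proteome.
    """
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    unknown = sorted(set(effect_spec) - {e.orf_id for e in cryptodb})
    if unknown:
        raise ValueError(f"effects on unknown cryptoDB entries: {unknown}")

    # per-entry usable peptides: tryptic >=8, unique in db, absent from proteome
    folded_aa = {e.orf_id: fold_il(e.aa_sequence) for e in cryptodb}
    prot_text = "|".join(fold_il(seq) for _, seq in proteome)
    usable: dict[str, list[str]] = {}
    for e in cryptodb:
        peps = []
        for pep in sorted(tryptic_peptides(e.aa_sequence, 8)):
            fpep = fold_il(pep)
            if prot_text and fpep in prot_text:
                continue
            owners = [oid for oid, faa in folded_aa.items() if fpep in faa]
            if owners == [e.orf_id]:
                peps.append(pep)
        usable[e.orf_id] = peps

    manifest = TruthManifest(seed=seed, params={"mean_count": str(noise.mean_count),
                                                "nb_dispersion": str(noise.nb_dispersion)})
    manifest.effects = dict(effect_spec)

    psms: list[PsmRecord] = []
    spec_counter = 0

    def emit(sample_id: str, peptide: str, q: float) -> None:
        nonlocal spec_counter
        spec_counter += 1
        psms.append(
            PsmRecord(sample_id, f"sp{spec_counter:07d}", peptide, q, float(rng.normal(50.0, 10.0)))
        )

    for orf_id, (kind, value) in sorted(effect_spec.items()):
        peps = usable[orf_id]
        if not peps:
            logger.warning("entry %s has no usable unique peptides; no signal emitted", orf_id)
            continue
        for d in design:
            if kind == "odds_ratio":
                p0 = noise.detect_prob_control
                odds = value * p0 / (1 - p0)
                p_det = odds / (1 + odds) if d.group == "case" else p0
                if rng.random() >= p_det:
                    continue
                count = 1 + _nb_draw(rng, max(noise.mean_count - 1.0, 0.0), noise.nb_dispersion)
            else:
                mean = _group_mean(kind, value, d.group, noise)
                count = _nb_draw(rng, mean, noise.nb_dispersion)
            for _ in range(count):
                emit(d.sample_id, peps[rng.integers(0, len(peps))], float(rng.uniform(0.0, noise.q_signal_max)))

    n_signal = len(psms)
    all_peps = [p for peps in usable.values() for p in peps]
    for _ in range(int(noise.decoy_fdr_frac * n_signal)):
        d = design[rng.integers(0, len(design))]
        emit(d.sample_id, all_peps[rng.integers(0, len(all_peps))], float(rng.uniform(0.11, 1.0)))
    if proteome:
        for _ in range(int(noise.canonical_frac * n_signal)):
            d = design[rng.integers(0, len(design))]
            acc, seq = proteome[rng.integers(0, len(proteome))]
            ln = int(rng.integers(9, 16))
            start = int(rng.integers(0, max(len(seq) - ln, 1)))
            emit(d.sample_id, seq[start : start + ln], float(rng.uniform(0.0, noise.q_signal_max)))
    for _ in range(int(noise.unmatched_frac * n_signal)):
        d = design[rng.integers(0, len(design))]
        pep = _random_aa(rng, 12)
        fpep = fold_il(pep)
        if (prot_text and fpep in prot_text) or any(fpep in faa for faa in folded_aa.values()):
            continue  # pragma: no cover - keep the row genuinely unmatched
        emit(d.sample_id, pep, float(rng.uniform(0.0, noise.q_signal_max)))
    return psms, manifest
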