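"""Synthetic V(D)J rearrangement simulator for the TRB locus.

Builds a configurable germline set mirroring the topology of the horse TRB
locus (a V cluster of subgroup families upstream of two D-J-C clusters,
plus an inverted 3' V gene) and simulates rearranged, C-spliced transcript
fragments: a functional V joined to a D and a J with exonuclease trimming
and non-templated (N) nucleotide addition at both junctions, windowed into
120-bp junction-spanning reads with substitution errors.  Every read links
back to a ground-truth record, which is what the clonotype pipeline's
recovery metrics are measured against.

Rearrangement classes follow the locus geometry: *intra* joins a D and J
of the same D-J-C cluster, *inter* joins TRBD1 to a cluster-2 J (direct
5'-to-3' joining across clusters), and *trans* joins TRBD2 to a cluster-1
J, which cannot arise by simple deletional joining.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .germline import (
    Functionality,
    GeneType,
    GermlineGene,
    GermlineSet,
    Orientation,
    RecombinationSignal,
    STOP_CODONS,
    check_j_motif,
    classify_functionality,
    identity_matrix,
    j_phe_offset,
    revcomp,
    translate,
)

__all__ = [
    "SimConfig",
    "TrimP",
    "MaxTrim",
    "RearrangementRecord",
    "SyntheticRead",
    "GenerationError",
    "build_default_germline",
    "simulate_rearrangement",
    "emit_reads",
    "write_truth",
    "read_truth",
    "simulate_repertoire",
    "SimulationResult",
    "TRBD1_DEFAULT",
    "TRBD2_DEFAULT",
    "V_TAIL",
]

# Canonical default D genes: G-rich stretches of 12 (TRBD1) and 17 (TRBD2)
# nt, readable through all three frames (encoding glycine runs), sharing
# no substring of length >= 4, so a >=6 nt junction stretch identifies its
# D unambiguously and a chance straddle of one D's remnant with random N
# bases essentially never completes a 6-mer of the other D.
TRBD1_DEFAULT = "GGGACAGGGGGC"
TRBD2_DEFAULT = "GGTGGCGGAGGTGGCAC"

# Default germline V nucleotides following the 2nd-CYS codon (the V
# contribution to the CDR3).  Every simulated V gene receives its own
# distinct 9-nt tail of this shape, always free of G so that a masked V
# prefix can never extend into the G-leading D genes during junction
# decomposition; G-freedom also keeps the tail free of cysteine codons
# and of stop codons in every frame.
V_TAIL = "ACCTCCACC"

_VR_CODONS = 108          # V-REGION codons; 2nd-CYS at codon 104 (0-based)
_CYS1_CODON = 22
_TRP_CODON = 40
_CYS2_CODON = 104
_BARCODE_CODONS = tuple(range(96, 104))   # third-position member barcode
_LPART1_CODONS = 16       # ATG + 15 codons

_SAFE_CODONS = sorted(set(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
) - STOP_CODONS)
# codons excluded from anchor scan windows so planted anchors stay unique
_SAFE_NO_CYS = [c for c in _SAFE_CODONS if c not in ("TGT", "TGC")]
_SAFE_NO_TRP = [c for c in _SAFE_CODONS if c != "TGG"]


class GenerationError(RuntimeError):
    """Raised when the germline constraints cannot be met after retries."""


@dataclass(frozen=True)
class TrimP:
    """Per-end geometric trimming parameters (success probability p; the
    number of trimmed nucleotides is Geometric(p) - 1, i.e. p = 1 disables
    trimming at that end)."""

    v: float = 0.45
    d5: float = 0.45
    d3: float = 0.45
    # J genes are untrimmed by default: the extraction procedure keeps only
    # reads matching a J probe at 98-100% over the full probe, so observable
    # clonotypes carry (near-)intact J genes, as seen in the real survey.
    j: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v", "d5", "d3", "j"):
            p = getattr(self, name)
            if not 0 < p <= 1:
                raise ValueError(f"trim_geometric_p.{name} must be in (0, 1]")


@dataclass(frozen=True)
class MaxTrim:
    """Hard caps on trimming per end (nt)."""

    v: int = 9
    d5: int = 6
    d3: int = 6
    j: int = 4


@dataclass
class SimConfig:
    """Study conditions of the synthetic repertoire.

    The defaults describe a scaled-down TRB locus: six V subgroups with
    24 functional and 6 pseudogene members plus one inverted 3' V, two
    D genes of 12 and 17 nt, and two D-J-C clusters carrying 6 and 7 J
    genes.  The rearrangement class mix (intra, inter, trans) and the
    D-usage bias toward TRBD2 mirror the fractions observed in the horse
    splenic clonotype survey.
    """

    n_v_functional: int = 24
    n_v_pseudo: int = 6
    n_subgroups: int = 6
    d_lengths: tuple[int, int] = (12, 17)
    j_per_cluster: tuple[int, int] = (6, 7)
    class_mix: tuple[float, float, float] = (0.813, 0.157, 0.030)
    d_usage: tuple[float, float] = (0.395, 0.605)
    trim_geometric_p: TrimP = field(default_factory=TrimP)
    max_trim: MaxTrim = field(default_factory=MaxTrim)
    n_insert_length_dist: dict[int, float] | None = None  # default uniform 0..6
    read_length: int = 120
    min_c_in_read: int = 9
    substitution_error_rate: float = 0.0005
    seed: int = 0
    verify_identity: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.read_length < 60:
            raise ValueError("read_length must be >= 60")
        if any(d <= 0 for d in self.d_lengths):
            raise ValueError("d_lengths must be positive")
        if self.n_subgroups < 1:
            raise ValueError("n_subgroups must be >= 1")
        if self.n_insert_length_dist is None:
            self.n_insert_length_dist = {k: 1 / 7 for k in range(7)}
        total = sum(self.n_insert_length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("n_insert_length_dist must sum to 1")


@dataclass
class RearrangementRecord:
    """Ground truth for one simulated rearrangement."""

    record_id: str
    v_name: str
    d_name: str | None
    j_name: str
    c_name: str
    v_trim: int
    d5_trim: int
    d3_trim: int
    j_trim: int
    n1_seq: str
    n2_seq: str
    rearrangement_class: str        # intra | inter | trans
    junction_nt: str                # trimmed-V-end + n1 + trimmed-D + n2 + trimmed-J-start
    in_frame: bool
    productive: bool
    d_retained: str = ""
    v_subgroup: str = ""


@dataclass
class SyntheticRead:
    read_id: str
    seq: str
    strand: str                      # '+' or '-'
    truth_id: str


# ---------------------------------------------------------------------------
# Random sequence helpers
# ---------------------------------------------------------------------------

def _stopfree_seq(rng: np.random.Generator, n: int) -> str:
    """Sequence containing no stop-codon substring in any frame (after a T
    only C or T may follow, which forbids TA* and TG*)."""
    out = []
    prev = ""
    for _ in range(n):
        pool = "CT" if prev == "T" else "ACGT"
        b = pool[rng.integers(len(pool))]
        out.append(b)
        prev = b
    return "".join(out)


def _gfree_stopfree_seq(rng: np.random.Generator, n: int, first: str | None = None) -> str:
    """G-free sequence with no stop substring (used for J CDR3 portions so
    they can never harbour a G-rich D-like stretch)."""
    out = []
    prev = ""
    if first is not None:
        out.append(first)
        prev = first
    while len(out) < n:
        pool = "CT" if prev == "T" else "ACT"
        b = pool[rng.integers(len(pool))]
        out.append(b)
        prev = b
    return "".join(out)


def _pick(rng: np.random.Generator, pool: list[str]) -> str:
    return pool[rng.integers(len(pool))]


def _consensus_rs(rng: np.random.Generator, spacer_len: int) -> RecombinationSignal:
    spacer = _stopfree_seq(rng, spacer_len)
    return RecombinationSignal("CACAGTG", spacer, "ACAAAAACC")


def _barcode_codewords(rng: np.random.Generator, n: int) -> list[list[str]]:
    """Third-position barcodes over the 8 codons preceding the 2nd-CYS.

    One codeword per V gene, greedily sampled with pairwise Hamming
    distance >= 4, so any two V genes differ by more than the default
    V-call margin within the read window even when trimming leaves only
    the last ~30 V nucleotides.
    """
    words: list[np.ndarray] = []
    for _ in range(20000):
        cand = rng.integers(0, 4, size=8)
        if all((cand != w).sum() >= 4 for w in words):
            words.append(cand)
            if len(words) == n:
                break
    else:
        raise GenerationError("could not build enough distinct V barcodes")
    return [["ACGT"[b] for b in w] for w in words]


def _v_codon_pool(codon_idx: int) -> list[str]:
    lo1, hi1 = 15, 30
    lo2, hi2 = 33, 48
    if lo1 <= codon_idx <= hi1 or codon_idx >= _VR_CODONS - 12:
        return _SAFE_NO_CYS
    if lo2 <= codon_idx <= hi2:
        return _SAFE_NO_TRP
    return _SAFE_CODONS


def _v_ancestor(rng: np.random.Generator) -> list[str]:
    """Ancestral V gene as a codon list: L-PART1 (16 codons, ATG first) +
    V-REGION (108 codons with planted anchors, barcode slots and tail).

    All subgroup families derive from this ancestor, as real V subgroups
    derive from duplications: keeping families homologous (rather than
    independent random sequences) keeps the full-length alignment optimal
    so the identity measure behaves as it does on real genes.
    """
    codons = ["ATG"] + [_pick(rng, _SAFE_CODONS) for _ in range(_LPART1_CODONS - 1)]
    for idx in range(_VR_CODONS):
        codons.append(_pick(rng, _v_codon_pool(idx)))
    vr = _LPART1_CODONS
    codons[vr + _CYS1_CODON] = "TGT"
    codons[vr + _TRP_CODON] = "TGG"
    codons[vr + _CYS2_CODON] = "TGC"
    for k, c in enumerate(_BARCODE_CODONS):
        codons[vr + c] = "CCA"          # overwritten per member by barcode
    codons[vr + 105:vr + 108] = [V_TAIL[0:3], V_TAIL[3:6], V_TAIL[6:9]]
    return codons


_PROTECTED = {0} | {_LPART1_CODONS + c for c in
                    (_CYS1_CODON, _TRP_CODON, _CYS2_CODON, 105, 106, 107,
                     *_BARCODE_CODONS)}


def _mutate_codons(rng: np.random.Generator, proto: list[str],
                   rate: float) -> list[str]:
    """Resample a fraction of the unprotected codons (anchors, barcode
    slots, tail and start codon never move)."""
    codons = list(proto)
    free = [i for i in range(len(codons)) if i not in _PROTECTED]
    k = max(1, int(round(rate * len(free))))
    for i in rng.choice(len(free), size=k, replace=False):
        idx = free[i]
        pool = (_v_codon_pool(idx - _LPART1_CODONS)
                if idx >= _LPART1_CODONS else _SAFE_CODONS)
        codons[idx] = _pick(rng, pool)
    return codons


# Divergence calibrated once for the identity measure (global alignment,
# free end gaps): members stay well above the 75% subgroup threshold and
# families stay below 70% with little pair-to-pair variance, because the
# diverged positions are shared by all families and carry mutually distant
# codons rather than independent random draws.
FAMILY_SHARED_FRACTION = 0.43
MEMBER_DIVERGENCE = 0.06


def _distinct_codons(rng: np.random.Generator, pool: list[str], n: int
                     ) -> list[str]:
    """n codons from ``pool`` with pairwise Hamming distance >= 2."""
    for _ in range(400):
        chosen: list[str] = []
        for i in rng.permutation(len(pool)):
            c = pool[int(i)]
            if all(sum(a != b for a, b in zip(c, d)) >= 2 for d in chosen):
                chosen.append(c)
                if len(chosen) == n:
                    return chosen
    raise GenerationError(f"cannot pick {n} mutually distant codons")


def _family_prototypes(rng: np.random.Generator, ancestor: list[str],
                       n_fam: int) -> list[list[str]]:
    """Family prototypes diverging from the ancestor at a common set of
    positions, with per-family codons chosen mutually distant so every
    family pair sits at the same, controlled nucleotide identity."""
    protos = [list(ancestor) for _ in range(n_fam)]
    free = [i for i in range(len(ancestor)) if i not in _PROTECTED]
    n_div = int(round((1.0 - FAMILY_SHARED_FRACTION) * len(free)))
    div_idx = sorted(free[int(i)] for i in
                     rng.choice(len(free), size=n_div, replace=False))
    for idx in div_idx:
        pool = (_v_codon_pool(idx - _LPART1_CODONS)
                if idx >= _LPART1_CODONS else _SAFE_CODONS)
        codons = _distinct_codons(rng, pool, n_fam)
        for f in range(n_fam):
            protos[f][idx] = codons[f]
    return protos


def _apply_barcode(codons: list[str], codeword: list[str]) -> list[str]:
    codons = list(codons)
    for pos, base in zip(_BARCODE_CODONS, codeword):
        codons[_LPART1_CODONS + pos] = "CC" + base
    return codons


def _make_v_gene(rng: np.random.Generator, name: str, subgroup: str,
                 codons: list[str], defect: str | None = None,
                 orientation: Orientation = Orientation.FORWARD,
                 tail: str | None = None) -> GermlineGene:
    codons = list(codons)
    vr = _LPART1_CODONS
    if tail is not None:
        codons[vr + 105:vr + 108] = [tail[0:3], tail[3:6], tail[6:9]]
    if defect == "internal_stop":
        codons[vr + 50] = "TAA"
    elif defect == "missing_start":
        codons[0] = "ATA"
    elif defect == "terminal_stop":
        codons[vr + 107] = "TAA"
    seq = "".join(codons)
    if defect == "frameshift":
        cut = _LPART1_CODONS * 3 + 150
        seq = seq[:cut] + seq[cut + 1:]
    gene = GermlineGene(
        name=name, gene_type=GeneType.V, coding_nt=seq,
        rs_3prime=_consensus_rs(rng, 23), subgroup=subgroup,
        v_region_start=_LPART1_CODONS * 3, orientation=orientation,
    )
    gene.functionality = classify_functionality(gene).status
    return gene


def _make_d_genes(rng: np.random.Generator, lengths: tuple[int, int]
                  ) -> list[GermlineGene]:
    if tuple(lengths) == (12, 17):
        seqs = [TRBD1_DEFAULT, TRBD2_DEFAULT]
    else:
        for _ in range(200):
            seqs = []
            for L in lengths:
                # G-rich, T-free (hence stop-free in every frame)
                s = "".join(_pick(rng, ["G", "G", "G", "A", "C"]) for _ in range(L))
                seqs.append(s)
            kmers = [{s[i:i + 6] for i in range(len(s) - 5)} for s in seqs]
            if len(seqs) < 2 or not (kmers[0] & kmers[1]):
                break
        else:
            raise GenerationError("could not build D genes with distinct 6-mers")
    genes = []
    for i, s in enumerate(seqs, start=1):
        genes.append(GermlineGene(
            name=f"TRBD{i}", gene_type=GeneType.D, coding_nt=s,
            rs_5prime=_consensus_rs(rng, 12), rs_3prime=_consensus_rs(rng, 23),
            cluster_id=i,
        ))
    return genes


def _make_j_gene(rng: np.random.Generator, cluster: int, idx: int,
                 pre_len: int, total_len: int) -> GermlineGene:
    """One TRBJ gene: a G-free CDR3 contribution, the FGXG motif, and a
    codon tail ending in C (so the J/C boundary can never straddle a stop)."""
    pre = _gfree_stopfree_seq(rng, pre_len, first="T")
    f_codon = ["TTT", "TTC"][idx % 2]
    x_codon = _pick(rng, [c for c in _SAFE_CODONS if "G" not in c])
    g2 = ["GGA", "GGG", "GGC", "GGT"][idx % 4]
    motif = f_codon + "GGC" + x_codon + g2
    post_len = total_len - pre_len - len(motif)
    if post_len < 3:
        raise ValueError("J gene length budget too small")
    post = "".join(_pick(rng, _SAFE_CODONS) for _ in range(post_len // 3 + 1))
    post = post[:post_len - 1] + "C"
    nt = pre + motif + post
    assert len(nt) == total_len
    return GermlineGene(
        name=f"TRBJ{cluster}-{idx + 1}", gene_type=GeneType.J, coding_nt=nt,
        rs_5prime=_consensus_rs(rng, 12), cluster_id=cluster,
    )


def _best_ungapped_identity(probe: str, target: str) -> float:
    """Best percent identity of ``probe`` slid ungapped over ``target``
    (every shift, overhangs count as mismatches), over the full probe."""
    best = 0
    for off in range(-len(probe) + 1, len(target)):
        matches = sum(
            1 for i, ch in enumerate(probe)
            if 0 <= off + i < len(target) and target[off + i] == ch)
        best = max(best, matches)
    return 100.0 * best / len(probe)


def _make_c_genes(rng: np.random.Generator, exon_len: int = 90
                  ) -> list[GermlineGene]:
    c1 = _stopfree_seq(rng, exon_len)
    c2 = list(c1)
    for pos in (4, 40, 70):          # one early mismatch distinguishes C1/C2
        for alt in "ACGT":
            if alt == c1[pos]:
                continue
            trial = c2.copy()
            trial[pos] = alt
            s = "".join(trial)
            if not any(stop in s for stop in STOP_CODONS):
                c2 = trial
                break
    genes = []
    for i, s in enumerate((c1, "".join(c2)), start=1):
        genes.append(GermlineGene(name=f"TRBC{i}", gene_type=GeneType.C,
                                  coding_nt=s, cluster_id=i))
    return genes


def build_default_germline(config: SimConfig) -> GermlineSet:
    """Build the synthetic germline locus described by ``config``.

    Deterministic given ``config.seed``.  V genes fall into
    ``n_subgroups`` families whose intra-family identity exceeds 75% and
    whose inter-family identity stays below 70% (verified post hoc with the
    same identity measure the classifier uses, with bounded retries); the
    two D genes have the configured lengths and G-rich composition; the two
    D-J-C clusters carry motif-complete J genes of 47-53 nt and one C gene
    each; all recombination signals are consensus.  One functional V gene
    carries the in-frame terminal stop codon that IMGT still classes as
    functional, and the locus ends with an inverted pseudogene V.
    """
    ss = np.random.SeedSequence(config.seed)
    for attempt, child in enumerate(ss.spawn(4)):
        rng = np.random.default_rng(child)
        try:
            return _build_germline_once(rng, config)
        except GenerationError:
            if attempt == 3:
                raise
    raise GenerationError("unreachable")


def _build_germline_once(rng: np.random.Generator, config: SimConfig) -> GermlineSet:
    genes: list[GermlineGene] = []
    n_fun, n_pse, n_sub = config.n_v_functional, config.n_v_pseudo, config.n_subgroups
    fam_functional = [n_fun // n_sub + (1 if i < n_fun % n_sub else 0)
                      for i in range(n_sub)]
    fam_pseudo = [n_pse // n_sub + (1 if i < n_pse % n_sub else 0)
                  for i in range(n_sub)]
    defect_cycle = ["internal_stop", "frameshift", "missing_start"]
    family_of: dict[str, int] = {}
    terminal_used = False
    ancestor = _v_ancestor(rng)
    prototypes = _family_prototypes(rng, ancestor, n_sub + 1)
    codewords = iter(_barcode_codewords(rng, n_fun + n_pse + 1))
    tails: set[str] = set()

    def fresh_tail() -> str:
        # per-gene CDR3 tail so distinct V genes never share a junction
        for _ in range(200):
            t = _gfree_stopfree_seq(rng, 9)
            if t not in tails:
                tails.add(t)
                return t
        raise GenerationError("could not draw distinct V tails")
    for fam in range(n_sub):
        proto = prototypes[fam]
        subgroup = f"TRBV{fam + 1}"
        member = 0
        for k in range(fam_functional[fam]):
            member += 1
            codons = _apply_barcode(_mutate_codons(rng, proto, MEMBER_DIVERGENCE),
                                    next(codewords))
            defect = None
            if not terminal_used and fam == 0 and k == fam_functional[fam] - 1:
                defect = "terminal_stop"
                terminal_used = True
            g = _make_v_gene(rng, f"{subgroup}-{member}", subgroup, codons,
                             defect, tail=fresh_tail())
            if g.functionality is not Functionality.F:
                raise GenerationError(f"{g.name} failed functionality check")
            family_of[g.name] = fam
            genes.append(g)
        for k in range(fam_pseudo[fam]):
            member += 1
            codons = _apply_barcode(_mutate_codons(rng, proto, MEMBER_DIVERGENCE),
                                    next(codewords))
            g = _make_v_gene(rng, f"{subgroup}-{member}", subgroup, codons,
                             defect_cycle[k % 3], tail=fresh_tail())
            if g.functionality is not Functionality.P:
                raise GenerationError(f"{g.name} expected pseudogene")
            family_of[g.name] = fam
            genes.append(g)

    if config.verify_identity and len(family_of) > 1:
        v_list = [g for g in genes]
        mat = identity_matrix([g.coding_nt for g in v_list])
        for i in range(len(v_list)):
            for j in range(i + 1, len(v_list)):
                same = family_of[v_list[i].name] == family_of[v_list[j].name]
                ident = mat[i, j]
                if same and ident <= 75.0:
                    raise GenerationError(
                        f"intra-family identity {ident:.1f} <= 75 for "
                        f"{v_list[i].name}/{v_list[j].name}")
                if not same and ident >= 70.0:
                    raise GenerationError(
                        f"inter-family identity {ident:.1f} >= 70 for "
                        f"{v_list[i].name}/{v_list[j].name}")

    d_genes = _make_d_genes(rng, config.d_lengths)
    # all within the 47-53 nt band; >= 50 so the 98% probe threshold
    # tolerates one substitution anywhere in the probe
    j_len_cycle = [50, 51, 52, 53, 50, 52, 51]
    pre_cycle = [14, 15, 16]
    c_genes = _make_c_genes(rng)
    cluster_genes: list[GermlineGene] = []
    for cluster, n_j in enumerate(config.j_per_cluster, start=1):
        cluster_genes.append(d_genes[cluster - 1])
        for k in range(n_j):
            for _ in range(20):
                jg = _make_j_gene(rng, cluster, k, pre_cycle[k % 3],
                                  j_len_cycle[k % 7])
                if check_j_motif(jg)["motif_found"]:
                    break
            else:
                raise GenerationError("could not build a motif-complete J gene")
            cluster_genes.append(jg)
        cluster_genes.append(c_genes[cluster - 1])
    if len(config.j_per_cluster) != 2:
        raise GenerationError("exactly two D-J-C clusters are supported")

    # distinctness of J probes: the probe scan is an ungapped full-probe
    # comparison, so no probe may reach high identity at any offset
    # against another J gene
    j_list = [g for g in cluster_genes if g.gene_type is GeneType.J]
    for a in j_list:
        for b in j_list:
            if a is b:
                continue
            if _best_ungapped_identity(b.coding_nt, a.coding_nt) >= 90.0:
                raise GenerationError("J probes too similar")

    inv_proto = prototypes[n_sub]
    inverted = _make_v_gene(rng, f"TRBV{n_sub + 24}", f"TRBV{n_sub + 24}",
                            _apply_barcode(inv_proto, next(codewords)), "internal_stop",
                            orientation=Orientation.INVERTED)
    return GermlineSet(genes + cluster_genes + [inverted])


# ---------------------------------------------------------------------------
# Rearrangement simulation
# ---------------------------------------------------------------------------

_CLASSES = ("intra", "inter", "trans")


def _geom_trim(rng: np.random.Generator, p: float, cap: int) -> int:
    if p >= 1.0:
        return 0
    return min(int(rng.geometric(p)) - 1, cap)


def _n_insert(rng: np.random.Generator, dist: dict[int, float]) -> str:
    lengths = sorted(dist)
    probs = np.array([dist[k] for k in lengths], dtype=float)
    n = int(rng.choice(lengths, p=probs / probs.sum()))
    return "".join("ACGT"[rng.integers(4)] for _ in range(n))


def _j_pre_length(j_gene: GermlineGene) -> int:
    """Nucleotides of a J gene preceding its J-PHE codon (its CDR3 part)."""
    return j_phe_offset(j_gene)


def simulate_rearrangement(germline: GermlineSet, config: SimConfig,
                           rng: np.random.Generator,
                           record_id: str = "t000000") -> RearrangementRecord:
    """Sample one V-D-J rearrangement with trimming and N-addition.

    The class (intra / inter / trans) is drawn from ``config.class_mix``;
    the V is uniform over functional V genes; D and J are chosen
    consistently with the class, with intra-cluster joins biased by
    ``config.d_usage``.  Trims are geometric per end (capped) and the two N
    regions have uniform base composition.  The record stores the junction
    decomposition and frame/productivity ground truth.
    """
    if not germline.functional_v:
        raise ValueError("germline has no functional V genes")
    cls = _CLASSES[int(rng.choice(3, p=np.asarray(config.class_mix)))]
    if cls == "intra":
        du = np.asarray(config.d_usage, dtype=float)
        cluster = int(rng.choice([1, 2], p=du / du.sum()))
        d_cluster = j_cluster = cluster
    elif cls == "inter":
        d_cluster, j_cluster = 1, 2
    else:
        d_cluster, j_cluster = 2, 1
    v = germline.functional_v[int(rng.integers(len(germline.functional_v)))]
    d = germline.d_by_cluster[d_cluster]
    j_pool = germline.j_by_cluster[j_cluster]
    j = j_pool[int(rng.integers(len(j_pool)))]
    c = germline.c_by_cluster[j_cluster]

    tp, mt = config.trim_geometric_p, config.max_trim
    v_trim = _geom_trim(rng, tp.v, min(mt.v, len(V_TAIL)))
    d5 = _geom_trim(rng, tp.d5, mt.d5)
    d3 = _geom_trim(rng, tp.d3, min(mt.d3, len(d.coding_nt) - d5 - 1))
    j_pre = _j_pre_length(j)
    j_trim = _geom_trim(rng, tp.j, min(mt.j, j_pre - 1))
    n1 = _n_insert(rng, config.n_insert_length_dist)
    n2 = _n_insert(rng, config.n_insert_length_dist)

    v_tail = v.coding_nt[len(v.coding_nt) - len(V_TAIL):]
    v_end = v_tail[: len(V_TAIL) - v_trim]
    d_ret = d.coding_nt[d5: len(d.coding_nt) - d3]
    j_start = j.coding_nt[j_trim:j_pre]
    junction = v_end + n1 + d_ret + n2 + j_start
    in_frame = len(junction) % 3 == 0
    productive = in_frame and "*" not in translate(junction)
    return RearrangementRecord(
        record_id=record_id, v_name=v.name, d_name=d.name, j_name=j.name,
        c_name=c.name, v_trim=v_trim, d5_trim=d5, d3_trim=d3, j_trim=j_trim,
        n1_seq=n1, n2_seq=n2, rearrangement_class=cls, junction_nt=junction,
        in_frame=in_frame, productive=productive, d_retained=d_ret,
        v_subgroup=v.subgroup or "",
    )


def spliced_transcript(record: RearrangementRecord, germline: GermlineSet
                       ) -> tuple[str, int, int, int]:
    """Rebuild the rearranged, C-spliced transcript for a record.

    Returns ``(transcript, cys_pos, f_pos, c_start)`` where ``cys_pos`` is
    the 0-based position of the 2nd-CYS codon, ``f_pos`` of the J-PHE codon
    and ``c_start`` of the first C-gene base.
    """
    v = germline[record.v_name]
    j = germline[record.j_name]
    c = germline[record.c_name]
    v_part = v.coding_nt[: len(v.coding_nt) - record.v_trim]
    j_part = j.coding_nt[record.j_trim:]
    d_ret = record.d_retained
    transcript = v_part + record.n1_seq + d_ret + record.n2_seq + j_part + c.coding_nt
    cys_pos = (v.v_region_start or 0) + 3 * _CYS2_CODON
    j_pre = _j_pre_length(j)
    f_pos = (len(v_part) + len(record.n1_seq) + len(d_ret)
             + len(record.n2_seq) + (j_pre - record.j_trim))
    c_start = len(transcript) - len(c.coding_nt)
    return transcript, cys_pos, f_pos, c_start


def emit_reads(records: list[RearrangementRecord], germline: GermlineSet,
               config: SimConfig, rng: np.random.Generator,
               copies: int = 1) -> tuple[list[SyntheticRead], int]:
    """Window each record's transcript into junction-spanning reads.

    The window of ``config.read_length`` nt is centred on the junction
    midpoint, then shifted minimally so the read keeps the full CDR3 (with
    its 2nd-CYS codon) and at least ``config.min_c_in_read`` nt of the C
    gene.  Substitution errors are applied at the configured rate and each
    read is emitted on a uniform random strand.  Returns the reads and the
    number of records skipped because no valid window exists.
    """
    reads: list[SyntheticRead] = []
    skipped = 0
    L = config.read_length
    for rec in records:
        transcript, cys_pos, f_pos, c_start = spliced_transcript(rec, germline)
        if len(transcript) < L:
            skipped += 1
            continue
        mid = (cys_pos + 3 + f_pos) // 2
        start0 = mid - L // 2
        lower = c_start + config.min_c_in_read - L
        upper = min(cys_pos, len(transcript) - L)
        start = min(max(start0, lower, 0), upper) if lower <= upper else -1
        if start < 0 or start + L > len(transcript) or start > cys_pos:
            skipped += 1
            continue
        for _ in range(copies):
            seq = transcript[start:start + L]
            if config.substitution_error_rate > 0:
                seq = _add_errors(seq, config.substitution_error_rate, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            reads.append(SyntheticRead(
                read_id=f"r{len(reads):06d}|{rec.record_id}", seq=seq,
                strand=strand, truth_id=rec.record_id))
    return reads, skipped


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        alts = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = alts[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "record_id", "v_name", "d_name", "j_name", "c_name", "v_trim",
    "d5_trim", "d3_trim", "j_trim", "n1_seq", "n2_seq",
    "rearrangement_class", "junction_nt", "in_frame", "productive",
    "d_retained", "v_subgroup",
]


def truth_table(records: list[RearrangementRecord]) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in _TRUTH_COLUMNS} for r in records]
    df = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    return df


def write_truth(records: list[RearrangementRecord], path) -> None:
    """Write the ground-truth table as TSV (header-only when empty)."""
    truth_table(records).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[RearrangementRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(RearrangementRecord(
            record_id=row["record_id"], v_name=row["v_name"],
            d_name=row["d_name"] or None, j_name=row["j_name"],
            c_name=row["c_name"], v_trim=int(row["v_trim"]),
            d5_trim=int(row["d5_trim"]), d3_trim=int(row["d3_trim"]),
            j_trim=int(row["j_trim"]), n1_seq=row["n1_seq"],
            n2_seq=row["n2_seq"],
            rearrangement_class=row["rearrangement_class"],
            junction_nt=row["junction_nt"],
            in_frame=row["in_frame"] == "True",
            productive=row["productive"] == "True",
            d_retained=row["d_retained"], v_subgroup=row["v_subgroup"],
        ))
    return records


# ---------------------------------------------------------------------------
# One-call simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    germline: GermlineSet
    records: list[RearrangementRecord]
    reads: list[SyntheticRead]
    skipped: int

    @property
    def truth(self) -> pd.DataFrame:
        return truth_table(self.records)


def simulate_repertoire(config: SimConfig, n_records: int,
                        germline: GermlineSet | None = None,
                        copies: int = 1) -> SimulationResult:
    """Build (or reuse) a germline set, simulate ``n_records``
    rearrangements and emit windowed reads.  Fully deterministic under
    ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    _, rear_seed, read_seed = ss.spawn(3)
    if germline is None:
        germline = build_default_germline(config)
    rng = np.random.default_rng(rear_seed)
    records = [simulate_rearrangement(germline, config, rng, f"t{i:06d}")
               for i in range(n_records)]
    read_rng = np.random.default_rng(read_seed)
    reads, skipped = emit_reads(records, germline, config, read_rng, copies)
    return SimulationResult(germline=germline, records=records, reads=reads,
                            skipped=skipped)
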