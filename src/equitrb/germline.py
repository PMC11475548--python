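"""Germline TRB gene models and classification.

The T-cell receptor beta locus is built from four kinds of germline
segments: variable (TRBV), diversity (TRBD), joining (TRBJ) and constant
(TRBC) genes.  This module models individual germline genes, scores their
recombination signals (heptamer/nonamer with 12- or 23-nt spacers),
classifies functionality with IMGT-style rules (F / ORF / P), clusters V
genes into subgroups by nucleotide identity, and locates the conserved
V-region anchors (1st-CYS, conserved TRP, 2nd-CYS) and the TRBJ FGXG motif
that bound the CDR3.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneType",
    "Functionality",
    "Defect",
    "Orientation",
    "RecombinationSignal",
    "GermlineGene",
    "FunctionalityCall",
    "AnchorSet",
    "AnchorWindows",
    "FunctionalityRules",
    "AlignmentScoring",
    "pairwise_identity",
    "identity_matrix",
    "cluster_subgroups",
    "find_anchors",
    "classify_functionality",
    "validate_rs",
    "check_j_motif",
    "translate",
    "revcomp",
    "RS_HEPTAMER_CONSENSUS",
    "RS_NONAMER_CONSENSUS",
]

RS_HEPTAMER_CONSENSUS = "CACAGTG"
RS_NONAMER_CONSENSUS = "ACAAAAACC"

STOP_CODONS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def translate(nt: str) -> str:
    """Translate a nucleotide string codon by codon (trailing partial codon
    ignored; codons with non-ACGT characters yield 'X')."""
    aa = []
    for i in range(0, len(nt) - 2, 3):
        aa.append(_CODON_TABLE.get(nt[i:i + 3], "X"))
    return "".join(aa)


def revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class GeneType(str, enum.Enum):
    V = "V"
    D = "D"
    J = "J"
    C = "C"


class Functionality(str, enum.Enum):
    F = "F"      # functional
    ORF = "ORF"  # open reading frame with atypical features
    P = "P"      # pseudogene


class Orientation(str, enum.Enum):
    FORWARD = "forward"
    INVERTED = "inverted"


class Defect(str, enum.Enum):
    MISSING_START = "missing_start"
    FRAMESHIFT = "frameshift"
    INTERNAL_STOP = "internal_stop"
    TERMINAL_STOP_ONLY = "terminal_stop_only"
    DEFECTIVE_SPLICE = "defective_splice"
    DEFECTIVE_RS = "defective_rs"
    MISSING_ANCHOR = "missing_anchor"


@dataclass(frozen=True)
class RecombinationSignal:
    """Heptamer + 12/23-nt spacer + nonamer flanking a recombining segment."""

    heptamer: str
    spacer: str
    nonamer: str

    def __post_init__(self) -> None:
        if len(self.heptamer) != 7:
            raise ValueError(f"heptamer must be 7 nt, got {len(self.heptamer)}")
        if len(self.nonamer) != 9:
            raise ValueError(f"nonamer must be 9 nt, got {len(self.nonamer)}")
        # spacer lengths other than 12/23 are representable (they occur in
        # defective signals) but fail validate_rs and the gene-level checks

    @property
    def spacer_length(self) -> int:
        return len(self.spacer)

    @property
    def obeys_12_23(self) -> bool:
        return self.spacer_length in (12, 23)


@dataclass
class GermlineGene:
    """One germline V, D, J or C gene.

    ``coding_nt`` holds the coding nucleotides: for V genes the
    L-PART1 + V-EXON concatenation with the V-REGION starting at
    ``v_region_start``; for D and J genes the coding region; for C genes
    the (first) exon used by the read-level pipeline.
    """

    name: str
    gene_type: GeneType
    coding_nt: str
    rs_5prime: RecombinationSignal | None = None
    rs_3prime: RecombinationSignal | None = None
    cluster_id: int | None = None
    subgroup: str | None = None
    functionality: Functionality = Functionality.F
    orientation: Orientation = Orientation.FORWARD
    v_region_start: int | None = None
    splice_valid: bool = True

    @property
    def v_region(self) -> str:
        if self.gene_type is not GeneType.V:
            raise ValueError(f"{self.name}: v_region only defined for V genes")
        start = self.v_region_start or 0
        return self.coding_nt[start:]

    def structural_problems(self, j_length_band: tuple[int, int] = (47, 53)) -> list[str]:
        """Check the structural invariants of the 12/23 rule and J length.

        Returns a list of human-readable problems (empty when the gene is
        structurally sound). V genes carry a 3' 23-spacer RS; D genes a 5'
        12-spacer and 3' 23-spacer RS; J genes a 5' 12-spacer RS.
        """
        problems: list[str] = []
        t = self.gene_type
        if t is GeneType.V:
            if self.rs_3prime is None or self.rs_3prime.spacer_length != 23:
                problems.append("V gene must carry a 3' 23-spacer RS")
        elif t is GeneType.D:
            if self.rs_5prime is None or self.rs_5prime.spacer_length != 12:
                problems.append("D gene must carry a 5' 12-spacer RS")
            if self.rs_3prime is None or self.rs_3prime.spacer_length != 23:
                problems.append("D gene must carry a 3' 23-spacer RS")
            if self.cluster_id is None:
                problems.append("D gene must belong to a D-J-C cluster")
        elif t is GeneType.J:
            if self.rs_5prime is None or self.rs_5prime.spacer_length != 12:
                problems.append("J gene must carry a 5' 12-spacer RS")
            if self.cluster_id is None:
                problems.append("J gene must belong to a D-J-C cluster")
            lo, hi = j_length_band
            if not lo <= len(self.coding_nt) <= hi:
                problems.append(
                    f"J coding length {len(self.coding_nt)} outside [{lo}, {hi}]"
                )
        elif t is GeneType.C:
            if self.cluster_id is None:
                problems.append("C gene must belong to a D-J-C cluster")
        return problems


@dataclass(frozen=True)
class FunctionalityCall:
    status: Functionality
    defects: tuple[Defect, ...] = ()

    def __post_init__(self) -> None:
        if self.status is Functionality.P and not self.defects:
            raise ValueError("pseudogene call requires at least one defect")
        if self.status is Functionality.F and any(
            d is not Defect.TERMINAL_STOP_ONLY for d in self.defects
        ):
            raise ValueError("functional call may only carry terminal_stop_only")


@dataclass(frozen=True)
class AnchorSet:
    """Positions (0-based codon indices within the V-REGION) of the three
    conserved V anchors; ``found`` records per-anchor success."""

    cys23_pos: int | None
    trp41_pos: int | None
    cys104_pos: int | None
    found: dict[str, bool] = field(default_factory=dict)

    @property
    def all_found(self) -> bool:
        return all(self.found.get(k, False) for k in ("cys23", "trp41", "cys104"))


@dataclass(frozen=True)
class AnchorWindows:
    """Codon windows (0-based, inclusive) scanned for the V anchors."""

    cys23: tuple[int, int] = (15, 30)
    trp41: tuple[int, int] = (33, 48)
    cys104_tail: int = 12  # 2nd-CYS = last TGT/TGC in the final N codons


@dataclass(frozen=True)
class FunctionalityRules:
    """Switchable IMGT-style functionality rules.

    Pseudogene rules: frameshift, internal stop, missing start, defective
    splice, missing anchor.  ORF rule: recombination signal below the
    conservation threshold.  A stop codon confined to the last V-REGION
    codon is a non-defect (the rearrangement usually deletes it).
    """

    check_frameshift: bool = True
    check_internal_stop: bool = True
    check_missing_start: bool = True
    check_splice: bool = True
    check_anchors: bool = True
    check_rs: bool = True
    rs_threshold: float = 0.75
    anchor_windows: AnchorWindows = AnchorWindows()


# ---------------------------------------------------------------------------
# Pairwise nucleotide identity (global alignment, free end gaps)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentScoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


_MAX_LEN = 2000
_K_M = 1 << 13          # weight of the match count in the packed DP value
_K_S = 1 << 25          # weight of the alignment score
_C0 = 1 << 12           # column-count offset (columns stored as C0 - c)

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i


def _encode_seq(seq: str) -> np.ndarray:
    if not seq:
        raise ValueError("empty sequence")
    if len(seq) > _MAX_LEN:
        raise ValueError(f"sequence longer than supported maximum {_MAX_LEN}")
    arr = _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq.upper()) - set("ACGTN"))
        raise ValueError(f"sequence contains characters outside ACGTN: {bad}")
    return arr


def _decode_identity(best: np.ndarray) -> np.ndarray:
    """Unpack identity percentages from packed DP optima."""
    best = np.asarray(best, dtype=np.int64)
    r = best % _K_S
    m = r // _K_M
    c = _C0 - (r % _K_M)
    with np.errstate(divide="ignore", invalid="ignore"):
        ident = np.where(c > 0, 100.0 * m / np.maximum(c, 1), 0.0)
    return ident


def _dp_identity_batch(A: np.ndarray, B: np.ndarray,
                       scoring: AlignmentScoring) -> np.ndarray:
    """Packed wavefront DP over a batch of same-shape sequence pairs.

    A: (P, la) and B: (P, lb) encoded sequences.  The packed int64 cell value
    is score*K_S + matches*K_M + (C0 - columns): maximising it maximises the
    alignment score, then the match count, then minimises the core column
    count, which makes the reported identity deterministic under ties.
    Leading/trailing gaps are free (cells in row/column 0 stay at the base
    value; the optimum is taken over the last row and column).
    """
    P, la = A.shape
    lb = B.shape[1]
    md = scoring.match * _K_S + _K_M - 1
    xd = scoring.mismatch * _K_S - 1
    gd = scoring.gap * _K_S - 1
    eq = (A[:, :, None] == B[:, None, :]) & (A[:, :, None] != 4) & (B[:, None, :] != 4)
    S = np.where(eq, md, xd)
    H = np.full((P, la + 1, lb + 1), _C0, dtype=np.int64)
    for d in range(2, la + lb + 1):
        ilo = max(1, d - lb)
        ihi = min(la, d - 1)
        if ilo > ihi:
            continue
        i = np.arange(ilo, ihi + 1)
        j = d - i
        diag = H[:, i - 1, j - 1] + S[:, i - 1, j - 1]
        up = H[:, i - 1, j] + gd
        left = H[:, i, j - 1] + gd
        H[:, i, j] = np.maximum(diag, np.maximum(up, left))
    best = np.maximum(H[:, la, :].max(axis=1), H[:, :, lb].max(axis=1))
    return _decode_identity(best)


def pairwise_identity(seq_a: str, seq_b: str,
                      scoring: AlignmentScoring | None = None) -> float:
    """Percent nucleotide identity from a global alignment with free end gaps.

    Identity = 100 x matches / aligned columns, where the aligned columns
    exclude the unpenalised end-gap overhangs.  'N' matches nothing.  The
    result is symmetric and deterministic: among optimal-score alignments the
    one with the most matches (and, among those, the fewest core columns) is
    reported.
    """
    scoring = scoring or AlignmentScoring()
    a = _encode_seq(seq_a)
    b = _encode_seq(seq_b)
    return float(_dp_identity_batch(a[None, :], b[None, :], scoring)[0])


def identity_matrix(seqs: list[str], scoring: AlignmentScoring | None = None,
                    batch_size: int = 32) -> np.ndarray:
    """Symmetric matrix of pairwise identities over ``seqs``.

    Pairs are grouped by length so the wavefront DP can run batched; the
    result is identical to calling :func:`pairwise_identity` per pair.
    """
    scoring = scoring or AlignmentScoring()
    n = len(seqs)
    enc = [_encode_seq(s) for s in seqs]
    out = np.full((n, n), 100.0)
    groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = (i, j) if len(enc[i]) >= len(enc[j]) else (j, i)
            groups.setdefault((len(enc[a]), len(enc[b])), []).append((a, b))
    for (la, lb), pairs in groups.items():
        for k0 in range(0, len(pairs), batch_size):
            chunk = pairs[k0:k0 + batch_size]
            A = np.stack([enc[a] for a, _ in chunk])
            B = np.stack([enc[b] for _, b in chunk])
            idents = _dp_identity_batch(A, B, scoring)
            for (a, b), v in zip(chunk, idents):
                out[a, b] = out[b, a] = v
    return out


# ---------------------------------------------------------------------------
# Subgroup clustering
# ---------------------------------------------------------------------------

def cluster_subgroups(v_genes: list[GermlineGene], threshold: float = 75.0,
                      scoring: AlignmentScoring | None = None,
                      label_format: str = "S{}") -> dict[str, str]:
    """Cluster V genes into subgroups by nucleotide identity.

    Two genes sharing > ``threshold`` percent identity over the coding region
    (L-PART1 + V-EXON) belong to the same subgroup; subgroups are the
    single-linkage connected components, so a pair of members may fall below
    the threshold as long as a chain of above-threshold links connects them.
    Labels are assigned in order of each component's first gene in the input
    (genomic) order.
    """
    if not v_genes:
        return {}
    for g in v_genes:
        if g.gene_type is not GeneType.V:
            raise ValueError(f"{g.name}: cluster_subgroups only accepts V genes")
    names = [g.name for g in v_genes]
    mat = identity_matrix([g.coding_nt for g in v_genes], scoring)

    parent = list(range(len(v_genes)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(v_genes)):
        for j in range(i + 1, len(v_genes)):
            if mat[i, j] > threshold:
                parent[find(i)] = find(j)

    label_of_root: dict[int, str] = {}
    mapping: dict[str, str] = {}
    next_label = 1
    for idx, name in enumerate(names):
        root = find(idx)
        if root not in label_of_root:
            label_of_root[root] = label_format.format(next_label)
            next_label += 1
        mapping[name] = label_of_root[root]
    return mapping


# ---------------------------------------------------------------------------
# Anchors and functionality
# ---------------------------------------------------------------------------

def _first_codon_in(v_region: str, window: tuple[int, int],
                    codons: set[str]) -> int | None:
    lo, hi = window
    n_codons = len(v_region) // 3
    for idx in range(lo, min(hi, n_codons - 1) + 1):
        if v_region[idx * 3:idx * 3 + 3] in codons:
            return idx
    return None


def find_anchors(v_region_nt: str, windows: AnchorWindows | None = None,
                 frame_offset: int = 0) -> AnchorSet:
    """Locate the conserved V-REGION anchors by codon scan.

    1st-CYS (around IMGT position 23) is the first TGT/TGC codon in its
    window, the conserved TRP (around 41) the first TGG in its window, and
    the 2nd-CYS (IMGT 104) the last TGT/TGC among the final codons.  Codon
    indices are 0-based within the (frame-shifted) V-REGION; anchors that
    cannot be located are reported as not found rather than guessed.
    """
    windows = windows or AnchorWindows()
    region = v_region_nt[frame_offset:]
    region = region[: len(region) - len(region) % 3]
    n_codons = len(region) // 3

    cys23 = _first_codon_in(region, windows.cys23, {"TGT", "TGC"})
    trp41 = _first_codon_in(region, windows.trp41, {"TGG"})
    cys104 = None
    for idx in range(n_codons - 1, max(n_codons - windows.cys104_tail, 0) - 1, -1):
        if region[idx * 3:idx * 3 + 3] in {"TGT", "TGC"}:
            cys104 = idx
            break
    found = {"cys23": cys23 is not None, "trp41": trp41 is not None,
             "cys104": cys104 is not None}
    return AnchorSet(cys23_pos=cys23, trp41_pos=trp41, cys104_pos=cys104,
                     found=found)


def validate_rs(rs: RecombinationSignal, threshold: float = 0.75
                ) -> tuple[float, bool]:
    """Score a recombination signal against the canonical consensus.

    The score is the number of heptamer positions matching CACAGTG plus the
    number of nonamer positions matching ACAAAAACC, divided by 16.  The
    spacer content is never scored, but the signal only passes if the spacer
    length obeys the 12/23 rule and the score reaches the threshold.
    """
    matches = sum(a == b for a, b in zip(rs.heptamer, RS_HEPTAMER_CONSENSUS))
    matches += sum(a == b for a, b in zip(rs.nonamer, RS_NONAMER_CONSENSUS))
    score = matches / 16.0
    passed = score >= threshold and rs.spacer_length in (12, 23)
    return score, passed


def check_j_motif(j_gene: GermlineGene) -> dict:
    """Scan a TRBJ gene for the canonical FGXG amino-acid motif.

    All three frames are scanned; the motif's presence defines J
    functionality and its phenylalanine is the J-PHE 118 anchor bounding the
    CDR3.  When several frames contain the motif the lowest frame index wins
    (donor-splice information is not modeled in this representation).
    Returns ``{"motif_found", "j_phe_codon_index", "frame"}``.
    """
    if j_gene.gene_type is not GeneType.J:
        raise ValueError(f"{j_gene.name}: check_j_motif only accepts J genes")
    nt = j_gene.coding_nt
    for frame in range(3):
        aa = translate(nt[frame:])
        for pos in range(len(aa) - 3):
            if (aa[pos] == "F" and aa[pos + 1] == "G" and aa[pos + 3] == "G"
                    and aa[pos + 2] != "*"):
                return {"motif_found": True, "j_phe_codon_index": pos,
                        "frame": frame}
    return {"motif_found": False, "j_phe_codon_index": None, "frame": -1}


def j_phe_offset(j_gene: GermlineGene) -> int:
    """Nucleotide offset of the J-PHE codon (the F of FGXG) within a J gene.

    Everything before this offset is the J gene's contribution to the CDR3.
    Raises if the gene lacks the motif.
    """
    m = check_j_motif(j_gene)
    if not m["motif_found"]:
        raise ValueError(f"{j_gene.name}: no FGXG motif")
    return m["frame"] + 3 * m["j_phe_codon_index"]


def _classify_v(gene: GermlineGene, rules: FunctionalityRules) -> FunctionalityCall:
    defects: list[Defect] = []
    v_region = gene.v_region
    start = gene.v_region_start or 0
    l_part1 = gene.coding_nt[:start]

    if rules.check_frameshift and len(v_region) % 3 != 0:
        defects.append(Defect.FRAMESHIFT)
    if rules.check_missing_start and l_part1 and not l_part1.startswith("ATG"):
        defects.append(Defect.MISSING_START)
    if rules.check_splice and not gene.splice_valid:
        defects.append(Defect.DEFECTIVE_SPLICE)

    terminal_stop = False
    if rules.check_internal_stop and len(v_region) >= 3:
        usable = v_region[: len(v_region) - len(v_region) % 3]
        n_codons = len(usable) // 3
        for idx in range(n_codons):
            if usable[idx * 3:idx * 3 + 3] in STOP_CODONS:
                if idx == n_codons - 1 and len(v_region) % 3 == 0:
                    terminal_stop = True
                else:
                    defects.append(Defect.INTERNAL_STOP)
                    break

    anchors = None
    if rules.check_anchors:
        anchors = find_anchors(v_region, rules.anchor_windows)
        if not anchors.all_found:
            defects.append(Defect.MISSING_ANCHOR)

    if defects:
        return FunctionalityCall(Functionality.P, tuple(dict.fromkeys(defects)))

    # open frame, anchors present: ORF if the recombination signal is poor
    if rules.check_rs and gene.rs_3prime is not None:
        _, rs_ok = validate_rs(gene.rs_3prime, rules.rs_threshold)
        if not rs_ok:
            return FunctionalityCall(Functionality.ORF, (Defect.DEFECTIVE_RS,))

    if terminal_stop:
        return FunctionalityCall(Functionality.F, (Defect.TERMINAL_STOP_ONLY,))
    return FunctionalityCall(Functionality.F, ())


def classify_functionality(gene: GermlineGene,
                           rules: FunctionalityRules | None = None
                           ) -> FunctionalityCall:
    """Classify a germline gene as F / ORF / P with IMGT-style rules.

    For V genes: pseudogene if the V-REGION frame is broken, an in-frame
    stop sits strictly before the last V-REGION codon, L-PART1 lacks the
    start codon, the splice is flagged defective, or a conserved anchor is
    missing; ORF if the frame is open but the 3' recombination signal falls
    below the conservation threshold; functional otherwise.  A stop codon
    confined to the last V-REGION codon alone yields F with the
    ``terminal_stop_only`` defect recorded (such a stop very frequently
    disappears during the V-(D)-J rearrangement).  For J genes the FGXG
    motif decides; D and C genes are functional unless their recombination
    signal fails.
    """
    rules = rules or FunctionalityRules()
    if not gene.coding_nt:
        raise ValueError(f"{gene.name}: gene without coding_nt")
    t = gene.gene_type
    if t is GeneType.V:
        return _classify_v(gene, rules)
    if t is GeneType.J:
        if check_j_motif(gene)["motif_found"]:
            return FunctionalityCall(Functionality.F, ())
        return FunctionalityCall(Functionality.P, (Defect.MISSING_ANCHOR,))
    if t is GeneType.D and rules.check_rs:
        for rs in (gene.rs_5prime, gene.rs_3prime):
            if rs is not None and not validate_rs(rs, rules.rs_threshold)[1]:
                return FunctionalityCall(Functionality.ORF, (Defect.DEFECTIVE_RS,))
    return FunctionalityCall(Functionality.F, ())


# ---------------------------------------------------------------------------
# Locus-level container
# ---------------------------------------------------------------------------

class GermlineSet:
    """A complete germline gene set (the locus) with convenience lookups.

    Gene order reflects genomic order.  D, J and C genes are indexed by
    their D-J-C cluster; V genes are split into functional and
    non-functional pools as classified by :func:`classify_functionality`.
    """

    def __init__(self, genes: list[GermlineGene]):
        self.genes = list(genes)
        self.by_name: dict[str, GermlineGene] = {}
        for g in self.genes:
            if g.name in self.by_name:
                raise ValueError(f"duplicate gene name {g.name}")
            self.by_name[g.name] = g
        self.v_genes = [g for g in self.genes if g.gene_type is GeneType.V]
        self.d_genes = [g for g in self.genes if g.gene_type is GeneType.D]
        self.j_genes = [g for g in self.genes if g.gene_type is GeneType.J]
        self.c_genes = [g for g in self.genes if g.gene_type is GeneType.C]
        self.functional_v = [g for g in self.v_genes
                             if g.functionality is Functionality.F]
        self.d_by_cluster = {g.cluster_id: g for g in self.d_genes}
        self.j_by_cluster: dict[int, list[GermlineGene]] = {}
        for g in self.j_genes:
            self.j_by_cluster.setdefault(g.cluster_id, []).append(g)
        self.c_by_cluster = {g.cluster_id: g for g in self.c_genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, name: str) -> GermlineGene:
        return self.by_name[name]

    def j_cluster(self, j_name: str) -> int:
        gene = self.by_name[j_name]
        if gene.gene_type is not GeneType.J or gene.cluster_id is None:
            raise ValueError(f"{j_name}: unknown J cluster")
        return gene.cluster_id
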