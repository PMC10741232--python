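"""Multifactor dimensionality reduction (MDR) from scratch.

MDR collapses a k-locus genotype table into one binary attribute: each
multi-locus genotype cell is labeled high-risk when its case:control
ratio reaches the overall ratio of the individuals entering the table,
and low-risk otherwise.  Candidate locus combinations are compared by
stratified 10-fold cross-validation — cells are labeled on 9/10 of the
data and the high/low rule is scored on the held-out tenth by balanced
accuracy — with cross-validation consistency (CVC, the number of folds
in which a combination is the best of its size) and a label-permutation
test completing the canonical procedure.  An entropy-based interaction
analysis (interaction information as a percentage of the class entropy)
summarises synergy and redundancy between markers.

Implementation notes: individuals with a missing genotype at any locus
of a combination are excluded from that combination's table only; fold
assignment is fixed once per search so comparisons across combinations
are paired; cell labeling ties (ratio exactly equal to threshold) go to
high-risk; cells unseen in training default to low-risk (an
``empty_cell`` flag switches to excluding them from scoring).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .panel import CASE, MISSING, GenotypePanel

EmptyCellPolicy = Literal["low", "exclude"]


# --------------------------------------------------------------------------
# cell tables and risk labels
# --------------------------------------------------------------------------

@dataclass
class CellTable:
    """Per-cell (case, control) counts for one locus combination."""

    combo: tuple[str, ...]
    cells: dict[tuple[int, ...], tuple[int, int]]
    threshold: float

    @property
    def n_cases(self) -> int:
        return sum(c for c, _ in self.cells.values())

    @property
    def n_controls(self) -> int:
        return sum(c for _, c in self.cells.values())


@dataclass
class RiskModel:
    """High/low-risk label per genotype cell."""

    combo: tuple[str, ...]
    label: dict[tuple[int, ...], str]
    threshold: float
    empty_cell: EmptyCellPolicy = "low"

    def predict(self, genotype: Sequence[int]) -> str | None:
        """'high'/'low' for a genotype tuple; None under the exclude policy."""
        lab = self.label.get(tuple(int(g) for g in genotype))
        if lab is None:
            return None if self.empty_cell == "exclude" else "low"
        return lab


@dataclass
class MdrModelReport:
    combo: tuple[str, ...]
    training_ba: float
    testing_ba: float
    cvc: int
    folds: int
    perm_p: float | None = None


@dataclass(frozen=True)
class ClassMetrics:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    pr_auc: float


@dataclass
class EntropyReport:
    """Main-effect and pairwise interaction information, % of class entropy."""

    main_ig: dict[str, float]
    pair_ig: dict[tuple[str, str], float]
    linkage: np.ndarray | None
    leaves: list[str]

    def newick(self) -> str:
        if self.linkage is None:
            return "(" + ",".join(self.leaves) + ");"
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.leaves[node.id]
            return f"({walk(node.left)},{walk(node.right)}):{node.dist:.4f}"

        return walk(tree) + ";"


# --------------------------------------------------------------------------
# internals
# --------------------------------------------------------------------------

def _combo_cells(panel: GenotypePanel, combo: Sequence[str]) -> tuple[np.ndarray, np.ndarray, int]:
    """(cell index, complete-data mask, n_cells) for a combination."""
    combo = tuple(combo)
    if len(combo) == 0 or len(set(combo)) != len(combo):
        raise ValueError("combo must be a non-empty set of distinct SNPs")
    cols = panel.genotypes[:, [panel.snp_index(s) for s in combo]]
    mask = (cols != MISSING).all(axis=1)
    ncells = 3 ** len(combo)
    weights = 3 ** np.arange(len(combo))
    cell = np.where(mask, cols.clip(min=0) @ weights, 0)
    return cell.astype(np.int64), mask, ncells


def _cell_tuple(index: int, k: int) -> tuple[int, ...]:
    out = []
    for _ in range(k):
        out.append(index % 3)
        index //= 3
    return tuple(out)


def stratified_folds(phenotype: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Seed-deterministic stratified fold ids (cases and controls split evenly)."""
    rng = np.random.default_rng(seed)
    fold_id = np.empty(len(phenotype), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(phenotype == cls)
        rng.shuffle(idx)
        fold_id[idx] = np.arange(len(idx)) % folds
    return fold_id


def _fold_class_cell_counts(
    cell: np.ndarray, y: np.ndarray, fold_id: np.ndarray, mask: np.ndarray,
    folds: int, ncells: int,
) -> np.ndarray:
    """T[f, c, cls] genotype-cell counts per fold, complete data only."""
    code = (fold_id[mask] * ncells + cell[mask]) * 2 + y[mask]
    return np.bincount(code, minlength=folds * ncells * 2).reshape(folds, ncells, 2)


def _ba_from_counts(high: np.ndarray, counts: np.ndarray) -> float:
    """Balanced accuracy of a high/low labeling against cell counts.

    ``high`` is a boolean per-cell array, ``counts`` a (ncells, 2) array of
    (control, case) counts.  Returns NaN when either class is absent.
    """
    n_ctrl, n_case = counts[:, 0].sum(), counts[:, 1].sum()
    if n_case == 0 or n_ctrl == 0:
        return float("nan")
    sens = counts[high, 1].sum() / n_case
    spec = counts[~high, 0].sum() / n_ctrl
    return float((sens + spec) / 2.0)


def _label_cells(train_counts: np.ndarray) -> np.ndarray:
    """High-risk mask per cell from training (control, case) counts.

    A cell is high when case/control >= threshold, the case:control ratio
    of all training individuals in the table; ties go high, zero-control
    cells with cases go high, empty cells go low.
    """
    tr_ctrl, tr_case = train_counts[:, 0].sum(), train_counts[:, 1].sum()
    nonempty = train_counts.sum(axis=1) > 0
    # case * N_ctrl >= control * N_case  <=>  case/control >= N_case/N_ctrl
    high = (train_counts[:, 1] * tr_ctrl >= train_counts[:, 0] * tr_case) & nonempty
    return high


# --------------------------------------------------------------------------
# public single-model operations
# --------------------------------------------------------------------------

def cell_counts(panel: GenotypePanel, combo: Sequence[str]) -> CellTable:
    """Case/control counts per multi-locus genotype cell.

    Only complete-data individuals for this combination enter; the risk
    threshold is their case:control ratio.
    """
    combo = tuple(combo)
    cell, mask, ncells = _combo_cells(panel, combo)
    if not mask.any():
        raise ValueError(f"every individual is missing a genotype in {combo}")
    y = panel.phenotype
    counts = np.bincount(cell[mask] * 2 + y[mask], minlength=ncells * 2).reshape(ncells, 2)
    n_ctrl, n_case = counts[:, 0].sum(), counts[:, 1].sum()
    cells = {
        _cell_tuple(i, len(combo)): (int(counts[i, 1]), int(counts[i, 0]))
        for i in range(ncells)
        if counts[i].sum() > 0
    }
    threshold = n_case / n_ctrl if n_ctrl > 0 else math.inf
    return CellTable(combo=combo, cells=cells, threshold=float(threshold))


def classify_cells(table: CellTable, empty_cell: EmptyCellPolicy = "low") -> RiskModel:
    """Label each observed cell high/low risk by the table's threshold."""
    if not table.cells:
        raise ValueError("cannot classify an empty cell table")
    n_case, n_ctrl = table.n_cases, table.n_controls
    label = {}
    for tup, (c_case, c_ctrl) in table.cells.items():
        label[tup] = "high" if c_case * n_ctrl >= c_ctrl * n_case else "low"
    return RiskModel(combo=table.combo, label=label, threshold=table.threshold,
                     empty_cell=empty_cell)


def balanced_accuracy(model: RiskModel, panel: GenotypePanel) -> float:
    """(sensitivity + specificity)/2 of the model's high=case prediction."""
    cell, mask, ncells = _combo_cells(panel, model.combo)
    k = len(model.combo)
    high = np.zeros(ncells, dtype=bool)
    known = np.zeros(ncells, dtype=bool)
    for i in range(ncells):
        lab = model.label.get(_cell_tuple(i, k))
        known[i] = lab is not None
        high[i] = lab == "high"
    if model.empty_cell == "exclude":
        mask = mask & known[cell]
    y = panel.phenotype
    counts = np.bincount(cell[mask] * 2 + y[mask], minlength=ncells * 2).reshape(ncells, 2)
    ba = _ba_from_counts(high, counts)
    if math.isnan(ba):
        warnings.warn("balanced accuracy undefined: one class absent")
    return ba


# --------------------------------------------------------------------------
# cross-validation
# --------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    training_ba: float
    testing_ba: float


def _cv_combo(
    T: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-fold (training BA, testing BA) from fold/cell/class counts."""
    folds = T.shape[0]
    total = T.sum(axis=0)
    train_ba = np.empty(folds)
    test_ba = np.empty(folds)
    for f in range(folds):
        train = total - T[f]
        high = _label_cells(train)
        train_ba[f] = _ba_from_counts(high, train)
        test_ba[f] = _ba_from_counts(high, T[f])
    return train_ba, test_ba


def cross_validate(
    panel: GenotypePanel,
    combo: Sequence[str],
    folds: int = 10,
    seed: int = 0,
    fold_id: np.ndarray | None = None,
) -> list[FoldResult]:
    """Stratified k-fold MDR evaluation of one locus combination.

    The high/low labeling is fitted on each training split and scored on
    the held-out fold by balanced accuracy.  ``fold_id`` lets a caller
    share one fold assignment across combinations (as :func:`mdr_search`
    does); otherwise folds are derived from ``seed``.  Folds whose test
    split lacks a class yield NaN testing BA and are skipped in averages.
    """
    combo = tuple(combo)
    if fold_id is None:
        fold_id = stratified_folds(panel.phenotype, folds, seed)
    cell, mask, ncells = _combo_cells(panel, combo)
    T = _fold_class_cell_counts(cell, panel.phenotype, fold_id, mask, folds, ncells)
    train_ba, test_ba = _cv_combo(T)
    out = [FoldResult(f, float(train_ba[f]), float(test_ba[f])) for f in range(folds)]
    if any(math.isnan(r.testing_ba) for r in out):
        warnings.warn(f"{combo}: some folds lack a class in the test split")
    return out


def permutation_pvalue(
    panel: GenotypePanel,
    combo: Sequence[str],
    n_perm: int = 1000,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Label-permutation p for one combination's mean CV testing BA.

    Case/control labels are permuted ``n_perm`` times; the full
    cross-validation testing BA is recomputed for each permutation using
    the original fold structure, and p = (r + 1)/(n_perm + 1) with r the
    number of permutations reaching the observed value.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    combo = tuple(combo)
    rng = np.random.default_rng(seed)
    fold_id = stratified_folds(panel.phenotype, folds, int(rng.integers(2**31 - 1)))
    cell, mask, ncells = _combo_cells(panel, combo)
    y = panel.phenotype
    T = _fold_class_cell_counts(cell, y, fold_id, mask, folds, ncells)
    observed = float(np.nanmean(_cv_combo(T)[1]))
    r = 0
    for _ in range(n_perm):
        yp = rng.permutation(y)
        Tp = _fold_class_cell_counts(cell, yp, fold_id, mask, folds, ncells)
        if float(np.nanmean(_cv_combo(Tp)[1])) >= observed - 1e-12:
            r += 1
    return (r + 1) / (n_perm + 1)


def mdr_search(
    panel: GenotypePanel,
    k_range: Sequence[int] = (1, 2, 3),
    folds: int = 10,
    seed: int = 0,
    n_perm: int = 0,
) -> tuple[list[MdrModelReport], MdrModelReport]:
    """Exhaustive MDR search over locus combinations of each size.

    One stratified fold assignment is drawn and shared by every
    combination, so fold-level comparisons are paired.  Per size, CVC
    counts the folds in which a combination attains the best training BA
    of its size; the size's candidate model maximises CVC (ties broken by
    mean testing BA), and the overall best model is the candidate with
    the highest CVC, ties broken by mean testing BA then fewer loci — the
    standard MDR selection by maximum cross-validation consistency and
    maximum balanced test accuracy, which prefers a consistent
    two-locus model over a larger one that wins testing accuracy by a
    hair in a single fold split.

    With ``n_perm`` > 0 the best model gets a search-wide permutation p:
    labels are permuted, the whole search (same combinations, same folds)
    is re-run, and the permutation statistic is the maximum mean testing
    BA over all combinations.  Recomputing the full search under each
    permutation keeps the p-value valid despite model selection.
    """
    snp_ids = panel.snp_ids
    rng = np.random.default_rng(seed)
    fold_id = stratified_folds(panel.phenotype, folds, int(rng.integers(2**31 - 1)))
    y = panel.phenotype

    combos: list[tuple[str, ...]] = []
    sizes: list[int] = []
    for k in k_range:
        if k < 1 or k > len(snp_ids):
            raise ValueError(f"combination size {k} invalid for {len(snp_ids)} SNPs")
        for combo in itertools.combinations(snp_ids, k):
            combos.append(combo)
            sizes.append(k)

    cells = []
    for combo in combos:
        cell, mask, ncells = _combo_cells(panel, combo)
        cells.append((cell, mask, ncells))

    train_mat = np.empty((len(combos), folds))
    test_mat = np.empty((len(combos), folds))
    for i, (cell, mask, ncells) in enumerate(cells):
        T = _fold_class_cell_counts(cell, y, fold_id, mask, folds, ncells)
        train_mat[i], test_mat[i] = _cv_combo(T)

    reports: list[MdrModelReport] = []
    best_per_size: list[MdrModelReport] = []
    for k in sorted(set(sizes)):
        rows = [i for i, s in enumerate(sizes) if s == k]
        sub_train = train_mat[rows]
        # CVC: per fold, which combo of this size has the best training BA
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fold_best = np.nanargmax(sub_train, axis=0)
        for pos, i in enumerate(rows):
            reports.append(
                MdrModelReport(
                    combo=combos[i],
                    training_ba=float(np.nanmean(train_mat[i])),
                    testing_ba=float(np.nanmean(test_mat[i])),
                    cvc=int((fold_best == pos).sum()),
                    folds=folds,
                )
            )
        best_per_size.append(
            max(
                (r for r in reports if len(r.combo) == k),
                key=lambda r: (r.cvc, r.testing_ba),
            )
        )

    overall = max(best_per_size, key=lambda r: (r.cvc, r.testing_ba, -len(r.combo)))

    if n_perm > 0:
        observed = overall.testing_ba
        r_count = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            best_perm = -np.inf
            for cell, mask, ncells in cells:
                Tp = _fold_class_cell_counts(cell, yp, fold_id, mask, folds, ncells)
                best_perm = max(best_perm, float(np.nanmean(_cv_combo(Tp)[1])))
            if best_perm >= observed - 1e-12:
                r_count += 1
        overall.perm_p = (r_count + 1) / (n_perm + 1)

    reports.sort(key=lambda r: (-r.testing_ba, -r.cvc, len(r.combo)))
    return reports, overall


# --------------------------------------------------------------------------
# whole-data classification metrics
# --------------------------------------------------------------------------

def class_metrics(model: RiskModel, panel: GenotypePanel) -> ClassMetrics:
    """Confusion-matrix metrics of the fitted model on a panel.

    Predictions: high-risk cell -> case.  The F1 score is the harmonic
    mean of precision and sensitivity; MCC is the standard Matthews
    coefficient (always within [-1, 1]); PR-AUC ranks individuals by
    their cell's training case proportion and is computed as average
    precision with step interpolation.
    """
    cell, mask, ncells = _combo_cells(panel, model.combo)
    k = len(model.combo)
    y = panel.phenotype[mask]
    cells = cell[mask]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both classes must be present")

    counts = np.bincount(cells * 2 + y, minlength=ncells * 2).reshape(ncells, 2)
    pred_high = np.array(
        [model.predict(_cell_tuple(i, k)) == "high" for i in range(ncells)]
    )
    tp = counts[pred_high, 1].sum()
    fp = counts[pred_high, 0].sum()
    fn = counts[~pred_high, 1].sum()
    tn = counts[~pred_high, 0].sum()

    acc = (tp + tn) / (tp + tn + fp + fn)
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    f1 = (
        2 * prec * sens / (prec + sens)
        if not math.isnan(prec) and prec + sens > 0
        else float("nan")
    )
    mcc_den = math.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = ((tp * tn - fp * fn) / mcc_den) if mcc_den else float("nan")

    # PR curve: score = cell case proportion; average precision, step interp.
    cell_total = counts.sum(axis=1)
    score_by_cell = np.where(cell_total > 0, counts[:, 1] / np.maximum(cell_total, 1), 0.0)
    scores = score_by_cell[cells]
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    scores_sorted = scores[order]
    tp_cum = np.cumsum(y_sorted)
    precision = tp_cum / (np.arange(len(y_sorted)) + 1)
    recall = tp_cum / y.sum()
    # average precision over threshold steps (last index of each distinct score)
    last_of_score = np.r_[scores_sorted[1:] != scores_sorted[:-1], True]
    rec_prev = 0.0
    ap = 0.0
    for i in np.flatnonzero(last_of_score):
        ap += (recall[i] - rec_prev) * precision[i]
        rec_prev = recall[i]
    return ClassMetrics(
        accuracy=float(acc),
        precision=float(prec),
        sensitivity=float(sens),
        specificity=float(spec),
        f1=float(f1),
        mcc=float(mcc),
        pr_auc=float(ap),
    )


# --------------------------------------------------------------------------
# entropy / interaction information
# --------------------------------------------------------------------------

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mutual_information(joint: np.ndarray) -> float:
    """I(X;Y) in bits from a joint count matrix."""
    total = joint.sum()
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    return hx + hy - hxy


def entropy_analysis(
    panel: GenotypePanel, snps: Sequence[str] | None = None
) -> EntropyReport:
    """Main-effect and pairwise interaction information, % of class entropy.

    With class variable C and SNPs A, B (plug-in entropies over complete
    pairs, log base 2): main IG(A) = I(A;C)/H(C) x 100; pairwise
    IG(A;B) = [I(A,B;C) - I(A;C) - I(B;C)]/H(C) x 100 — positive values
    mean synergy (the pair carries information neither SNP has alone),
    negative values redundancy.  The dendrogram clusters markers by
    average linkage on the dissimilarity 1 - |IG|/max|IG|.  Constant SNPs
    get main IG 0 and are excluded from clustering.
    """
    snps = list(snps) if snps is not None else panel.snp_ids
    if len(snps) < 2:
        raise ValueError("entropy analysis needs at least two SNPs")
    y = panel.phenotype
    h_c = _entropy(np.bincount(y, minlength=2))
    if h_c == 0:
        raise ValueError("class entropy is zero (single-class panel)")

    cols = {s: panel.column(s) for s in snps}
    main: dict[str, float] = {}
    usable: list[str] = []
    for s in snps:
        col = cols[s]
        ok = col != MISSING
        joint = np.zeros((3, 2))
        for g in (0, 1, 2):
            for c in (0, 1):
                joint[g, c] = np.sum((col == g) & (y == c) & ok)
        if len(np.unique(col[ok])) < 2:
            main[s] = 0.0
            continue
        main[s] = _mutual_information(joint) / h_c * 100.0
        usable.append(s)

    pair: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(usable, 2):
        ca, cb = cols[a], cols[b]
        ok = (ca != MISSING) & (cb != MISSING)
        h_c_ok = _entropy(np.bincount(y[ok], minlength=2))
        joint_a = np.zeros((3, 2))
        joint_b = np.zeros((3, 2))
        joint_ab = np.zeros((9, 2))
        for c in (0, 1):
            sel = ok & (y == c)
            joint_a[:, c] = np.bincount(ca[sel], minlength=3)[:3]
            joint_b[:, c] = np.bincount(cb[sel], minlength=3)[:3]
            joint_ab[:, c] = np.bincount(ca[sel] * 3 + cb[sel], minlength=9)[:9]
        if h_c_ok == 0:
            pair[(a, b)] = 0.0
            continue
        ig = (
            _mutual_information(joint_ab)
            - _mutual_information(joint_a)
            - _mutual_information(joint_b)
        )
        pair[(a, b)] = ig / h_c_ok * 100.0

    linkage_matrix = None
    if len(usable) >= 2 and pair:
        max_abs = max(abs(v) for v in pair.values())
        dim = len(usable)
        dist = np.zeros((dim, dim))
        for (a, b), v in pair.items():
            i, j = usable.index(a), usable.index(b)
            dist[i, j] = dist[j, i] = 1.0 - (abs(v) / max_abs if max_abs > 0 else 0.0)
        linkage_matrix = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return EntropyReport(main_ig=main, pair_ig=pair, linkage=linkage_matrix, leaves=usable)
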