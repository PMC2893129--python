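"""Evolution-score descriptors from position-specific scoring matrices.

An L x 20 matrix of log-odds substitution scores is standardized row-wise,
collapsed to a 20-component mean profile, and optionally augmented with
lag-correlation factors so that proteins of any length map to a fixed-length
vector of dimension 20 * (1 + lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..records import AMINO_ACIDS

#: Column order used by the PSI-BLAST ASCII matrix dialect.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Upper bound on the correlation tier count (shortest-chain constraint).
MAX_LAMBDA = 49


class PSSMParseError(ValueError):
    """Malformed ASCII scoring-matrix file; message carries the line number."""


class PSSMDimensionError(ValueError):
    """A raw matrix whose column count is not 20."""


class LambdaBoundError(ValueError):
    """A correlation tier count incompatible with the matrix length."""


@dataclass(frozen=True)
class PSSMatrix:
    """An L x 20 score matrix, columns in alphabetical single-letter order.

    ``standardized`` records whether rows have been centred/scaled; the
    standardization is idempotent by construction.
    """

    scores: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 20:
            raise PSSMDimensionError(
                f"expected an L x 20 matrix, got shape {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise PSSMDimensionError("matrix must have at least one position")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "scores", arr)

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class PsePSSMVector:
    """Fixed-length evolution descriptor: mean profile plus lag correlations.

    ``values`` concatenates the 20 per-amino-acid mean scores with one
    20-component correlation block per tier xi = 1..lambda, giving dimension
    20 * (1 + lambda).  At lambda = 0 the vector is exactly the mean profile.
    """

    lambda_: int
    values: np.ndarray
    mode: str = "psepssm"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if self.lambda_ < 0:
            raise LambdaBoundError("lambda must be non-negative")
        if vals.shape != (20 * (1 + self.lambda_),):
            raise ValueError(
                f"values must have dimension {20 * (1 + self.lambda_)}, "
                f"got {vals.shape}"
            )
        vals = vals.copy()
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    @property
    def dim(self) -> int:
        return int(self.values.size)

    def to_array(self) -> np.ndarray:
        return np.array(self.values)


def standardize_pssm(raw: np.ndarray | PSSMatrix) -> PSSMatrix:
    """Centre and scale each matrix row over its 20 amino acid columns.

    Every row x becomes (x - mean(x)) / sd(x) with the population standard
    deviation (divisor 20), so row means vanish and the transform is a no-op
    on already-standardized input.  Degenerate constant rows (sd = 0) map to
    all-zero rows, preserving the zero-mean contract.
    """
    if isinstance(raw, PSSMatrix):
        if raw.standardized:
            return raw
        arr = raw.scores
    else:
        arr = np.asarray(raw, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 20:
            raise PSSMDimensionError(
                f"expected an L x 20 matrix, got shape {arr.shape}"
            )
    means = arr.mean(axis=1, keepdims=True)
    sds = arr.std(axis=1, keepdims=True)  # population form, divisor 20
    centred = arr - means
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sds > 0, centred / sds, 0.0)
    return PSSMatrix(out, standardized=True)


def mean_profile(pssm: PSSMatrix) -> np.ndarray:
    """Average each amino acid column over all positions (20-vector)."""
    return pssm.scores.mean(axis=0)


def correlation_factor(pssm: PSSMatrix, j: int, xi: int) -> float:
    """Lag-``xi`` correlation factor for amino acid column ``j``.

    theta_j(xi) = mean over i of (score(i, j) - score(i + xi, j))^2,
    the squared-difference coupling of scores ``xi`` positions apart.
    """
    L = pssm.length
    if not 1 <= xi <= L - 1:
        raise LambdaBoundError(
            f"lag xi={xi} out of range [1, {L - 1}] for a length-{L} matrix"
        )
    col = pssm.scores[:, j]
    return float(np.mean((col[: L - xi] - col[xi:]) ** 2))


def _correlation_block(pssm: PSSMatrix, xi: int) -> np.ndarray:
    L = pssm.length
    diff = pssm.scores[: L - xi] - pssm.scores[xi:]
    return (diff**2).mean(axis=0)


def psepssm_vector(
    pssm: PSSMatrix, lambda_: int, max_lambda: int = MAX_LAMBDA
) -> PsePSSMVector:
    """Build the 20*(1+lambda) evolution descriptor from a standardized matrix.

    Concatenates the mean profile with one correlation block per tier
    xi = 1..lambda.  ``lambda_`` must be smaller than both the matrix length
    and ``max_lambda`` (the shortest admissible chain length bounds the tier
    count); lambda = 0 degenerates to the plain mean profile.
    """
    if lambda_ < 0:
        raise LambdaBoundError("lambda must be non-negative")
    if lambda_ > max_lambda:
        raise LambdaBoundError(
            f"lambda={lambda_} exceeds the configured bound {max_lambda} "
            "(must be smaller than the shortest chain length)"
        )
    if lambda_ >= pssm.length:
        raise LambdaBoundError(
            f"lambda={lambda_} must be smaller than the matrix length {pssm.length}"
        )
    blocks = [mean_profile(pssm)]
    for xi in range(1, lambda_ + 1):
        blocks.append(_correlation_block(pssm, xi))
    return PsePSSMVector(lambda_, np.concatenate(blocks))


def parse_pssm_ascii(text: str) -> np.ndarray:
    """Parse the first score block of a PSI-BLAST ASCII matrix file.

    Expects header lines, a column-header line naming >= 20 amino acid
    letters, then one line per position (index, residue, 20 integer scores;
    any further columns are ignored), and an optional statistics footer.
    Columns are remapped from the file's declared order to alphabetical
    single-letter order.  Returns an integer L x 20 array.
    """
    lines = text.splitlines()
    col_letters: list[str] = []
    header_idx = -1
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(
            len(t) == 1 and t in AMINO_ACIDS for t in tokens[:20]
        ):
            col_letters = tokens[:20]
            header_idx = i
            break
    if header_idx < 0:
        raise PSSMParseError("no amino acid column header line found")
    if len(set(col_letters)) != 20:
        raise PSSMParseError(
            f"line {header_idx + 1}: column header letters are not 20 distinct "
            "amino acids"
        )

    rows: list[list[int]] = []
    expected_pos = 1
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        tokens = line.split()
        if not tokens:
            if rows:
                break  # blank line after the matrix body starts the footer
            continue
        if not tokens[0].isdigit():
            if rows:
                break  # footer (Lambda/K statistics etc.)
            raise PSSMParseError(f"line {lineno}: expected a position row")
        if len(tokens) < 22:
            raise PSSMParseError(
                f"line {lineno}: truncated row ({len(tokens)} fields, need >= 22)"
            )
        if int(tokens[0]) != expected_pos:
            raise PSSMParseError(
                f"line {lineno}: position index {tokens[0]} out of sequence "
                f"(expected {expected_pos})"
            )
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PSSMParseError(f"line {lineno}: non-integer score ({exc})") from None
        rows.append(scores)
        expected_pos += 1
    if not rows:
        raise PSSMParseError("no score rows found")

    raw = np.array(rows, dtype=np.int64)
    remap = [col_letters.index(aa) for aa in AMINO_ACIDS]
    return raw[:, remap]


def format_pssm_ascii(matrix: np.ndarray, sequence: str) -> str:
    """Write an integer score matrix in the ASCII dialect ``parse_pssm_ascii``
    reads, using the conventional PSI-BLAST column order.

    ``matrix`` columns are taken in alphabetical order and remapped on output;
    ``sequence`` supplies the residue column and must match the matrix length.
    """
    arr = np.asarray(matrix)
    if arr.ndim != 2 or arr.shape[1] != 20:
        raise PSSMDimensionError(f"expected an L x 20 matrix, got shape {arr.shape}")
    if len(sequence) != arr.shape[0]:
        raise PSSMDimensionError(
            f"sequence length {len(sequence)} does not match matrix length "
            f"{arr.shape[0]}"
        )
    remap = [AMINO_ACIDS.index(aa) for aa in PSIBLAST_ORDER]
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "  ".join(PSIBLAST_ORDER),
    ]
    for i, row in enumerate(arr[:, remap], start=1):
        cells = " ".join(f"{int(v):3d}" for v in row)
        out.append(f"{i:5d} {sequence[i - 1]}  {cells}")
    out.append("")
    out.append("                      K         Lambda")
    out.append("Standard Ungapped    0.1337     0.3113")
    return "\n".join(out) + "\n"
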