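"""Reading and writing 12-lead ECG records in the Challenge header dialect.

Records pair a plain-text header (``.hea``) carrying per-lead gain/baseline,
demographics and a ``#Dx:`` diagnosis-code line with a signal matrix stored
either as a MATLAB ``.mat`` file (variable ``val``, leads x samples, raw ADC
units) or as a plain delimited text matrix.  Signals are converted to
millivolts on read — every threshold downstream is expressed in mV — and the
lead order is normalised to the standard I, II, III, aVR, aVL, aVF, V1–V6.

Sample indexing is 0-based throughout; time ``t = index / fs`` seconds.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.signal

logger = logging.getLogger(__name__)

#: Canonical 12-lead order used everywhere in the package.
LEAD_ORDER: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

_LEAD_ALIASES = {name.upper(): name for name in LEAD_ORDER}


class RecordFormatError(ValueError):
    """A header or signal file could not be parsed; names the offending field."""


class UnsupportedRecordError(ValueError):
    """Structurally valid record that this toolkit does not handle (e.g. not 12 leads)."""


@dataclass
class ECGRecord:
    """A 12-lead ECG: signal matrix in mV plus metadata.

    ``signals`` has shape ``(12, n_samples)`` with rows in :data:`LEAD_ORDER`.
    """

    signals: np.ndarray
    fs: float
    lead_names: tuple[str, ...] = LEAD_ORDER
    age: float | None = None
    sex: str | None = None
    dx_codes: list[str] = field(default_factory=list)
    record_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[0] != 12:
            raise UnsupportedRecordError(
                f"expected a 12 x n_samples signal matrix, got shape {self.signals.shape}"
            )
        if self.signals.shape[1] < 1:
            raise RecordFormatError("record contains no samples")
        if not np.all(np.isfinite(self.signals)):
            raise RecordFormatError("non-finite samples in signal matrix")
        if not self.fs > 0:
            raise RecordFormatError(f"sampling rate must be positive, got {self.fs}")
        self.lead_names = tuple(self.lead_names)

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Signal of a single lead by canonical name."""
        return self.signals[self.lead_names.index(name)]


@dataclass(frozen=True)
class VocabEntry:
    abbreviation: str
    codes: frozenset[str]
    name: str
    is_normal: bool


@dataclass
class ClassVocabulary:
    """Ordered 24-class scored label space with equivalent-class merging.

    Equivalent diagnosis pairs (complete RBBB / RBBB, PAC / SVPB, PVC / VEB)
    are single entries whose ``codes`` sets contain both members' codes, so any
    member code maps onto the same column index.
    """

    entries: list[VocabEntry]

    def __post_init__(self) -> None:
        abbrevs = [e.abbreviation for e in self.entries]
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("duplicate class abbreviations in vocabulary")
        self._by_code = {}
        for idx, e in enumerate(self.entries):
            for code in e.codes:
                if code in self._by_code:
                    raise ValueError(f"code {code} mapped to two classes")
                self._by_code[code] = idx
        self._by_abbrev = {e.abbreviation: i for i, e in enumerate(self.entries)}

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    @property
    def abbreviations(self) -> list[str]:
        return [e.abbreviation for e in self.entries]

    def index_of(self, abbreviation: str) -> int:
        return self._by_abbrev[abbreviation]

    def index_of_code(self, code: str) -> int | None:
        return self._by_code.get(code)

    @property
    def normal_class(self) -> str:
        """Abbreviation of the class flagged as normal rhythm (scoring baseline)."""
        for e in self.entries:
            if e.is_normal:
                return e.abbreviation
        raise ValueError("vocabulary has no class flagged as normal")

    @classmethod
    def load(cls, path: str | Path | None = None) -> "ClassVocabulary":
        """Load the vocabulary CSV; defaults to the bundled 24-class table."""
        if path is None:
            src = resources.files("ecgdx.data").joinpath("class_vocabulary.csv")
            text = src.read_text(encoding="utf-8")
        else:
            text = Path(path).read_text(encoding="utf-8")
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        entries = []
        for row in csv.DictReader(lines):
            entries.append(
                VocabEntry(
                    abbreviation=row["abbreviation"].strip(),
                    codes=frozenset(c.strip() for c in row["codes"].split(";") if c.strip()),
                    name=row["name"].strip(),
                    is_normal=row["is_normal"].strip() == "1",
                )
            )
        return cls(entries)


# ---------------------------------------------------------------------------
# Challenge-dialect header + signal reading


def _parse_gain_token(token: str) -> tuple[float, float | None, str]:
    """Parse ``gain(baseline)/units`` -> (gain, baseline or None, units)."""
    m = re.match(r"^(-?[\d.]+)(?:\(([-\d]+)\))?(?:/(\S+))?$", token)
    if not m:
        raise RecordFormatError(f"unparseable gain field: {token!r}")
    gain = float(m.group(1))
    baseline = float(m.group(2)) if m.group(2) is not None else None
    units = m.group(3) or "mV"
    return gain, baseline, units


def read_record(header_path: str | Path, signal_path: str | Path | None = None) -> ECGRecord:
    """Read a Challenge-dialect header + signal matrix into an :class:`ECGRecord`.

    Parameters
    ----------
    header_path:
        Path to the text header (``.hea``).  CRLF line endings are tolerated.
    signal_path:
        Optional explicit signal file.  By default the file named in the
        header is used, searched next to the header with ``.mat``, ``.csv``
        and ``.txt`` fallbacks.
    """
    header_path = Path(header_path)
    lines = [ln.strip() for ln in header_path.read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln]
    if not lines:
        raise RecordFormatError(f"{header_path}: empty header")

    head = lines[0].split()
    if len(head) < 4:
        raise RecordFormatError(f"{header_path}: first line needs 'id n_leads fs n_samples'")
    record_id = head[0]
    try:
        n_leads = int(head[1])
        fs = float(head[2])
        n_samples = int(head[3])
    except ValueError as exc:
        raise RecordFormatError(f"{header_path}: bad numeric field in first line: {exc}") from exc
    if n_leads != 12:
        raise UnsupportedRecordError(f"{record_id}: expected 12 leads, header declares {n_leads}")

    sig_lines = lines[1 : 1 + n_leads]
    if len(sig_lines) < n_leads:
        raise RecordFormatError(f"{record_id}: header declares {n_leads} leads, "
                                f"found {len(sig_lines)} signal lines")

    gains, baselines, leads, file_names = [], [], [], []
    for ln in sig_lines:
        tok = ln.split()
        if len(tok) < 3:
            raise RecordFormatError(f"{record_id}: short signal line: {ln!r}")
        file_names.append(tok[0])
        gain, baseline, _units = _parse_gain_token(tok[2])
        if gain == 0:
            raise RecordFormatError(f"{record_id}: zero gain in line {ln!r}")
        if baseline is None:
            # no parenthesised baseline -> ADC-zero field (5th token) if present
            baseline = float(tok[4]) if len(tok) > 4 else 0.0
        lead_raw = tok[-1].upper()
        if lead_raw not in _LEAD_ALIASES:
            raise RecordFormatError(f"{record_id}: unknown lead name {tok[-1]!r}")
        gains.append(gain)
        baselines.append(baseline)
        leads.append(_LEAD_ALIASES[lead_raw])
    if set(leads) != set(LEAD_ORDER):
        raise UnsupportedRecordError(f"{record_id}: leads {leads} do not form the standard 12-lead set")

    age = sex = None
    dx_codes: list[str] = []
    for ln in lines[1 + n_leads:]:
        if not ln.startswith("#"):
            continue
        body = ln.lstrip("#").strip()
        key, _, value = body.partition(":")
        key = key.strip().lower()
        value = value.strip()
        if key == "age":
            try:
                age = float(value)
            except ValueError:
                age = None
        elif key == "sex":
            sex = value if value and value.lower() not in ("unknown", "nan") else None
        elif key == "dx":
            dx_codes = [c.strip() for c in value.split(",") if c.strip()]

    raw = _load_signal_matrix(header_path, signal_path, file_names[0], n_leads, n_samples,
                              record_id)

    # mV conversion and canonical lead ordering
    signals = np.empty((12, raw.shape[1]))
    for i, lead in enumerate(leads):
        signals[LEAD_ORDER.index(lead)] = (raw[i] - baselines[i]) / gains[i]

    return ECGRecord(signals=signals, fs=fs, age=age, sex=sex, dx_codes=dx_codes,
                     record_id=record_id)


def _load_signal_matrix(header_path: Path, signal_path, declared_name: str,
                        n_leads: int, n_samples: int, record_id: str) -> np.ndarray:
    if signal_path is not None:
        candidates = [Path(signal_path)]
    else:
        candidates = [header_path.parent / declared_name]
        for ext in (".mat", ".csv", ".txt"):
            candidates.append(header_path.with_suffix(ext))
    path = next((p for p in candidates if p.exists()), None)
    if path is None:
        raise RecordFormatError(f"{record_id}: no signal file found (tried {candidates})")

    if path.suffix.lower() == ".mat":
        mat = scipy.io.loadmat(str(path))
        if "val" not in mat:
            raise RecordFormatError(f"{record_id}: .mat file lacks the 'val' variable")
        raw = np.asarray(mat["val"], dtype=float)
    else:
        raw = _read_text_matrix(path)

    if raw.ndim != 2:
        raise RecordFormatError(f"{record_id}: signal matrix is not 2-D")
    if raw.shape[0] != n_leads and raw.shape[1] == n_leads:
        raw = raw.T
    if raw.shape[0] != n_leads:
        raise RecordFormatError(
            f"{record_id}: signal shape {raw.shape} inconsistent with {n_leads} leads")
    if raw.shape[1] != n_samples:
        raise RecordFormatError(
            f"{record_id}: header declares {n_samples} samples, file has {raw.shape[1]}")
    return raw


def _read_text_matrix(path: Path) -> np.ndarray:
    """Plain delimited numeric matrix; tolerates CRLF, a header row and , ; tab or space."""
    text = path.read_text(encoding="utf-8")
    rows = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = re.split(r"[,;\t ]+", ln)
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            if not rows:
                continue  # header row
            raise RecordFormatError(f"{path}: non-numeric row {ln!r}")
    if not rows:
        raise RecordFormatError(f"{path}: no numeric data")
    return np.asarray(rows, dtype=float)


def read_matrix(path: str | Path, fs: float, record_id: str = "",
                lead_names: Sequence[str] = LEAD_ORDER) -> ECGRecord:
    """Fallback reader for a plain delimited lead matrix already in mV."""
    raw = _read_text_matrix(Path(path))
    if raw.shape[0] != 12 and raw.shape[1] == 12:
        raw = raw.T
    signals = np.empty_like(raw)
    for i, name in enumerate(lead_names):
        signals[LEAD_ORDER.index(_LEAD_ALIASES[name.upper()])] = raw[i]
    return ECGRecord(signals=signals, fs=fs,
                     record_id=record_id or Path(path).stem)


def write_record(rec: ECGRecord, base_path: str | Path, fmt: str = "csv",
                 gain: float = 1000.0) -> tuple[Path, Path]:
    """Write a record as Challenge-dialect header + signal matrix.

    ``fmt='csv'`` stores the raw ADC matrix as plain text (leads as rows);
    ``fmt='mat'`` stores a MATLAB ``val`` variable.  Values are quantised to
    integer ADC units at the given gain, so a read-back reproduces the signal
    to gain quantisation (0.5/gain mV).
    """
    base_path = Path(base_path)
    base_path.parent.mkdir(parents=True, exist_ok=True)
    ext = ".mat" if fmt == "mat" else ".csv"
    sig_path = base_path.with_suffix(ext)
    hea_path = base_path.with_suffix(".hea")

    raw = np.round(rec.signals * gain).astype(np.int64)
    lines = [f"{rec.record_id or base_path.stem} 12 {rec.fs:g} {rec.n_samples}"]
    for i, lead in enumerate(rec.lead_names):
        first = raw[i, 0] if rec.n_samples else 0
        lines.append(f"{sig_path.name} 16 {gain:g}(0)/mV 16 0 {first} 0 0 {lead}")
    lines.append(f"#Age: {'' if rec.age is None else int(rec.age)}")
    lines.append(f"#Sex: {rec.sex or 'Unknown'}")
    lines.append(f"#Dx: {','.join(rec.dx_codes)}")
    hea_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    if fmt == "mat":
        scipy.io.savemat(str(sig_path), {"val": raw})
    else:
        np.savetxt(sig_path, raw, fmt="%d", delimiter=",")
    return hea_path, sig_path


# ---------------------------------------------------------------------------
# Label mapping and resampling


def map_diagnoses(dx_codes: Sequence[str], vocab: ClassVocabulary) -> np.ndarray:
    """Binary label vector over the scored classes for a list of diagnosis codes.

    Equivalent classes share a column, so e.g. a complete-RBBB code and an
    RBBB code together light a single column.  Unscored codes are ignored
    (logged at debug level); the mapping is idempotent and order-independent.
    """
    y = np.zeros(vocab.n_classes, dtype=int)
    for code in dx_codes:
        idx = vocab.index_of_code(str(code).strip())
        if idx is None:
            logger.debug("unscored diagnosis code ignored: %s", code)
        else:
            y[idx] = 1
    return y


def resample_record(rec: ECGRecord, target_fs: float) -> ECGRecord:
    """Resample all leads to ``target_fs`` (polyphase); no-op at matching rate."""
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if not np.all(np.isfinite(rec.signals)):
        raise ValueError("cannot resample a record with non-finite samples")
    if np.isclose(rec.fs, target_fs):
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    signals = scipy.signal.resample_poly(rec.signals, frac.numerator, frac.denominator, axis=1)
    return ECGRecord(signals=signals, fs=target_fs, age=rec.age, sex=rec.sex,
                     dx_codes=list(rec.dx_codes), record_id=rec.record_id,
                     meta=dict(rec.meta))
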