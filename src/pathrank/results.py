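"""Result container shared by all pathway-level tests."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["TestResult"]


@dataclass
class TestResult:
    """Outcome of one set-level permutation test.

    Attributes
    ----------
    statistic
        Observed value of the test statistic (S, Q, or ES depending on the
        method).
    p_value
        Permutation p-value; always >= 1/n_perms_used because the observed
        labelling is counted in its own null distribution.
    n_perms_used
        Number of relabellings in the null distribution (C(n, n1) in the
        exhaustive regime, the permutation budget otherwise).
    method
        Short label: "rank", "modified_rank", "gsea" or "global".
    set_name, set_size
        The tested gene set and its on-array size N_G, when applicable.
    exhaustive
        Whether the null distribution enumerated every distinct relabelling
        (exact p-value) rather than sampling.
    extras
        Method-specific diagnostics (null moments, restandardization
        constants, fallback flags, ...).
    """

    statistic: float
    p_value: float
    n_perms_used: int
    method: str
    set_name: str | None = None
    set_size: int | None = None
    exhaustive: bool = False
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.n_perms_used >= 1 and self.p_value < 1.0 / self.n_perms_used - 1e-12:
            raise ValueError(
                f"p_value {self.p_value} below 1/{self.n_perms_used}; the observed "
                "labelling must be counted"
            )

    def summary(self) -> str:
        """Plain-text summary table in the style of a model-results object."""
        rows: list[tuple[str, str]] = [
            ("Method", self.method),
        ]
        if self.set_name is not None:
            rows.append(("Gene set", self.set_name))
        if self.set_size is not None:
            rows.append(("Set size (N_G)", str(self.set_size)))
        rows += [
            ("Statistic", f"{self.statistic:.6g}"),
            ("Permutation p-value", f"{self.p_value:.6g}"),
            ("Relabellings used", str(self.n_perms_used)),
            ("Null distribution", "exhaustive" if self.exhaustive else "sampled"),
        ]
        for key, val in self.extras.items():
            if isinstance(val, float):
                rows.append((key, f"{val:.6g}"))
            else:
                rows.append((key, str(val)))
        width = max(len(k) for k, _ in rows)
        lines = ["Pathway test result", "=" * (width + 24)]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()
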