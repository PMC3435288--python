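"""Internal-consistency checks of the published summary tables.

The published headline rankings derive from proprietary traffic data, so
they cannot be recomputed from raw inputs; what CAN be checked is that the
package's aggregation rules reproduce the arithmetic relationships among
the printed numbers themselves:

* each printed relative rate equals phi divided by the printed per-table
  mean, to the precision the printed phi allows;
* the complement-product combination applied to a truncated top-ten list
  is a tight lower bound on the printed overall rate (the omitted origins
  account for the gap);
* the Taiwan-to-Egypt rate ratio matches the published "more than 3 times"
  statement, and the ten-port journey span matches nine 7.9-day legs.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import reference as ref
from .summaries import combine_rates

__all__ = [
    "CheckResult",
    "melbourne_combined_rate",
    "korea_country_rate",
    "relative_rate_checks",
    "lower_bound_checks",
    "ratio_check",
    "journey_check",
    "all_checks",
]


@dataclass
class CheckResult:
    name: str
    computed: float
    published: float
    passed: bool
    detail: str = ""


def melbourne_combined_rate() -> float:
    """Complement-product of the ten published per-origin rates into
    Melbourne; a lower bound on the published overall Melbourne rate."""
    phis = [phi for _, _, phi, _ in ref.PER_DESTINATION_TOP10["Melbourne"]]
    return combine_rates(phis)


def korea_country_rate() -> float:
    """Republic-of-Korea country rate reconstructed from the published
    per-destination panels: combine each Korean port's rates across
    destinations, then combine across ports. Lower-bounds the published
    country rate (the panels are truncated top-ten lists)."""
    per_port = [combine_rates(v) for v in ref.korean_port_rates().values()]
    return combine_rates(per_port)


def _half_ulp(x: float) -> float:
    """Half a unit in the last printed decimal place of x."""
    s = f"{x!r}"
    decimals = len(s.split(".")[1]) if "." in s else 0
    return 0.5 * 10.0**-decimals


def _rounding_tol(phi: float, rel: float, mean: float) -> float:
    """Agreement tolerance at the printed precision: 0.1% relative,
    widened by the rounding floors of the three printed quantities (phi,
    the relative rate, and the table mean are each printed rounded, and a
    phi printed to two significant figures cannot pin its relative rate
    to 0.1%)."""
    return max(
        1e-3 * rel,
        _half_ulp(phi) / mean + _half_ulp(rel) + rel * _half_ulp(mean) / mean,
    )


def relative_rate_checks() -> list[CheckResult]:
    """phi / per-table mean reproduces every printed relative rate to the
    precision the printed values allow."""
    results = []
    tables = [
        ("country", ref.COUNTRY_RATES, ref.COUNTRY_MEAN_PHI),
        ("domestic_port", ref.DOMESTIC_PORT_RATES, ref.DOMESTIC_MEAN_PHI),
    ]
    for kind, table, mean in tables:
        for entity, (phi, rel_printed) in table.items():
            computed = phi / mean
            tol = _rounding_tol(phi, rel_printed, mean)
            results.append(
                CheckResult(
                    name=f"relative_rate:{kind}:{entity}",
                    computed=computed,
                    published=rel_printed,
                    passed=abs(computed - rel_printed) <= tol,
                    detail=f"phi={phi}, mean={mean}, tol={tol:.4g}",
                )
            )
    for dest, rows in ref.PER_DESTINATION_TOP10.items():
        for port, _, phi, rel_printed in rows:
            computed = phi / ref.PAIR_MEAN_PHI
            tol = _rounding_tol(phi, rel_printed, ref.PAIR_MEAN_PHI)
            results.append(
                CheckResult(
                    name=f"relative_rate:pair:{port}->{dest}",
                    computed=computed,
                    published=rel_printed,
                    passed=abs(computed - rel_printed) <= tol,
                    detail=f"phi={phi}, mean={ref.PAIR_MEAN_PHI}, tol={tol:.4g}",
                )
            )
    return results


def lower_bound_checks() -> list[CheckResult]:
    """Truncated-list complement products lower-bound the published
    overall rates (Melbourne port; Korea country)."""
    mel = melbourne_combined_rate()
    mel_published = ref.DOMESTIC_PORT_RATES["Melbourne"][0]
    kor = korea_country_rate()
    kor_published = ref.COUNTRY_RATES["Republic of Korea"][0]
    return [
        CheckResult(
            name="lower_bound:Melbourne_overall",
            computed=mel,
            published=mel_published,
            passed=mel <= mel_published,
            detail="complement-product of top-ten origins",
        ),
        CheckResult(
            name="lower_bound:Korea_country",
            computed=kor,
            published=kor_published,
            passed=kor <= kor_published,
            detail="per-port then cross-port complement-product",
        ),
    ]


def ratio_check() -> CheckResult:
    """The two top-ranked countries sit more than 3x above the third."""
    taiwan = ref.COUNTRY_RATES["Taiwan"][0]
    egypt = ref.COUNTRY_RATES["Egypt"][0]
    ratio = taiwan / egypt
    return CheckResult(
        name="ratio:Taiwan_vs_Egypt",
        computed=ratio,
        published=3.0,
        passed=ratio > 3.0,
        detail="published statement: more than 3 times the third-ranked country",
    )


def journey_check() -> CheckResult:
    """Nine legs of 7.9 days span the published 71-day ten-port history."""
    computed = 9 * ref.MEAN_LEG_DAYS
    return CheckResult(
        name="journey:ten_port_span_days",
        computed=computed,
        published=ref.TEN_STEP_JOURNEY_DAYS,
        passed=abs(computed - ref.TEN_STEP_JOURNEY_DAYS) <= 0.5,
        detail="9 * 7.9 = 71.1, printed rounded to 71",
    )


def all_checks() -> list[CheckResult]:
    return (
        relative_rate_checks() + lower_bound_checks() + [ratio_check(), journey_check()]
    )
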