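"""Published headline estimates from the original Khapra-beetle analysis
of the 2002–2007 Australian container-shipping network.

The underlying Lloyd's (LMIU) vessel-movement records are proprietary, so
these printed summary values cannot be regenerated from raw data here.
They serve two purposes: internal-consistency checks of the aggregation
rules (the complement-product combination applied to a truncated top-ten
list must lower-bound the published overall rate, and published relative
rates must equal phi divided by the published per-table mean), and
documentation of the traffic structure the synthetic generator emulates.

All arrival rates are per-pathway rates phi in [0, 1], estimated with
K = 2e6 realizations per origin.
"""

from __future__ import annotations

__all__ = [
    "COUNTRY_RATES",
    "COUNTRY_MEAN_PHI",
    "DOMESTIC_PORT_RATES",
    "DOMESTIC_MEAN_PHI",
    "PER_DESTINATION_TOP10",
    "PAIR_MEAN_PHI",
    "DEGREE_CENTRALITY",
    "COUNTRY_DEGREE_CENTRALITY",
    "MEAN_LEG_DAYS",
    "TEN_STEP_JOURNEY_DAYS",
    "NETWORK_SCALE",
    "korean_port_rates",
]

#: top ten source countries: overall arrival rate to all Australian ports
#: combined, with the published relative rate (phi / COUNTRY_MEAN_PHI)
COUNTRY_RATES: dict[str, tuple[float, float]] = {
    "Taiwan": (0.639, 9.054),
    "Republic of Korea": (0.594, 8.413),
    "Egypt": (0.155, 2.197),
    "Spain": (0.096, 1.355),
    "Saudi Arabia": (0.067, 0.953),
    "Sri Lanka": (0.066, 0.939),
    "India": (0.022, 0.315),
    "Yemen": (0.013, 0.186),
    "Turkey": (0.012, 0.168),
    "Pakistan": (0.009, 0.121),
}
#: mean phi over all network locations used for country relative rates
COUNTRY_MEAN_PHI = 0.0706

#: top ten Australian entry ports: overall arrival rate from all pest-range
#: origins combined, with the published relative rate
DOMESTIC_PORT_RATES: dict[str, tuple[float, float]] = {
    "Melbourne": (0.547, 8.921),
    "Botany Bay": (0.398, 6.487),
    "Brisbane": (0.390, 6.369),
    "Bell Bay": (0.217, 3.537),
    "Fremantle": (0.154, 2.517),
    "Adelaide": (0.095, 1.548),
    "Burnie": (0.050, 0.808),
    "Sydney": (0.026, 0.418),
    "Hobart": (0.014, 0.225),
    "Newcastle": (0.003, 0.047),
}
DOMESTIC_MEAN_PHI = 0.0613

#: per-destination top-ten origin ports: (origin port, country, phi,
#: published relative rate). Truncated lists — each destination has many
#: more origins below the tenth.
PER_DESTINATION_TOP10: dict[str, list[tuple[str, str, float, float]]] = {
    "Melbourne": [
        ("Busan", "KOR", 0.245, 94.601),
        ("Kaohsiung", "TWN", 0.227, 87.532),
        ("Keelung", "TWN", 0.075, 28.912),
        ("Damietta", "EGY", 0.039, 14.925),
        ("Colombo", "LKA", 0.021, 8.025),
        ("Jeddah", "SAU", 0.019, 7.157),
        ("Valencia", "ESP", 0.018, 6.916),
        ("Ulsan", "KOR", 0.017, 6.510),
        ("Port Said", "EGY", 0.011, 4.160),
        ("Barcelona", "ESP", 0.007, 2.569),
    ],
    "Botany Bay": [
        ("Kaohsiung", "TWN", 0.159, 61.473),
        ("Busan", "KOR", 0.158, 61.020),
        ("Keelung", "TWN", 0.053, 20.370),
        ("Damietta", "EGY", 0.025, 9.702),
        ("Colombo", "LKA", 0.013, 5.029),
        ("Jeddah", "SAU", 0.012, 4.704),
        ("Valencia", "ESP", 0.012, 4.593),
        ("Port Said", "EGY", 0.007, 2.673),
        ("Barcelona", "ESP", 0.005, 1.737),
        ("Ulsan", "KOR", 0.004, 1.500),
    ],
    "Brisbane": [
        ("Busan", "KOR", 0.160, 61.541),
        ("Kaohsiung", "TWN", 0.158, 61.098),
        ("Keelung", "TWN", 0.052, 20.153),
        ("Damietta", "EGY", 0.023, 9.043),
        ("Colombo", "LKA", 0.012, 4.453),
        ("Jeddah", "SAU", 0.010, 3.715),
        ("Valencia", "ESP", 0.009, 3.388),
        ("Port Said", "EGY", 0.005, 2.084),
        ("Gwangyang", "KOR", 0.004, 1.611),
        ("Ulsan", "KOR", 0.004, 1.497),
    ],
    "Bell Bay": [
        ("Busan", "KOR", 0.084, 32.346),
        ("Kaohsiung", "TWN", 0.070, 27.181),
        ("Keelung", "TWN", 0.023, 8.947),
        ("Damietta", "EGY", 0.012, 4.681),
        ("Ulsan", "KOR", 0.010, 3.849),
        ("Colombo", "LKA", 0.007, 2.511),
        ("Jeddah", "SAU", 0.006, 2.307),
        ("Valencia", "ESP", 0.006, 2.234),
        ("Port Said", "EGY", 0.003, 1.274),
        ("Barcelona", "ESP", 0.002, 0.803),
    ],
    "Fremantle": [
        ("Busan", "KOR", 0.051, 19.612),
        ("Kaohsiung", "TWN", 0.042, 16.364),
        ("Damietta", "EGY", 0.012, 4.653),
        ("Keelung", "TWN", 0.012, 4.614),
        ("Valencia", "ESP", 0.009, 3.369),
        ("Colombo", "LKA", 0.008, 2.917),
        ("Jeddah", "SAU", 0.007, 2.847),
        ("Port Said", "EGY", 0.004, 1.623),
        ("Barcelona", "ESP", 0.003, 1.014),
        ("Gwangyang", "KOR", 0.002, 0.814),
    ],
    "Adelaide": [
        ("Busan", "KOR", 0.029, 11.092),
        ("Kaohsiung", "TWN", 0.024, 9.246),
        ("Damietta", "EGY", 0.009, 3.558),
        ("Keelung", "TWN", 0.007, 2.678),
        ("Colombo", "LKA", 0.006, 2.197),
        ("Jeddah", "SAU", 0.005, 2.022),
        ("Valencia", "ESP", 0.005, 1.919),
        ("Port Said", "EGY", 0.003, 1.270),
        ("Barcelona", "ESP", 0.002, 0.615),
        ("Algeciras", "ESP", 0.001, 0.444),
    ],
    "Burnie": [
        ("Busan", "KOR", 0.0177, 6.8258),
        ("Kaohsiung", "TWN", 0.0149, 5.7627),
        ("Keelung", "TWN", 0.0049, 1.8764),
        ("Damietta", "EGY", 0.0026, 0.9920),
        ("Ulsan", "KOR", 0.0021, 0.8098),
        ("Colombo", "LKA", 0.0014, 0.5356),
        ("Jeddah", "SAU", 0.0012, 0.4785),
        ("Valencia", "ESP", 0.0012, 0.4650),
        ("Port Said", "EGY", 0.0007, 0.2591),
        ("Barcelona", "ESP", 0.0004, 0.1726),
    ],
    "Sydney": [
        ("Busan", "KOR", 0.0084, 3.2404),
        ("Kaohsiung", "TWN", 0.0077, 2.9682),
        ("Keelung", "TWN", 0.0025, 0.9821),
        ("Damietta", "EGY", 0.0018, 0.6922),
        ("Colombo", "LKA", 0.0009, 0.3436),
        ("Jeddah", "SAU", 0.0007, 0.2680),
        ("Valencia", "ESP", 0.0007, 0.2535),
        ("Port Said", "EGY", 0.0005, 0.1909),
        ("Ulsan", "KOR", 0.0004, 0.1463),
        ("Barcelona", "ESP", 0.0003, 0.1126),
    ],
    "Hobart": [
        ("Busan", "KOR", 0.0049, 1.8767),
        ("Kaohsiung", "TWN", 0.0041, 1.5825),
        ("Keelung", "TWN", 0.0014, 0.5427),
        ("Damietta", "EGY", 0.0007, 0.2684),
        ("Ulsan", "KOR", 0.0005, 0.2113),
        ("Colombo", "LKA", 0.0004, 0.1521),
        ("Jeddah", "SAU", 0.0004, 0.1357),
        ("Valencia", "ESP", 0.0004, 0.1350),
        ("Port Said", "EGY", 0.0002, 0.0833),
        ("Barcelona", "ESP", 0.0001, 0.0488),
    ],
    "Newcastle": [
        ("Busan", "KOR", 0.00089, 0.34454),
        ("Kaohsiung", "TWN", 0.00082, 0.31716),
        ("Keelung", "TWN", 0.00028, 0.10701),
        ("Damietta", "EGY", 0.00018, 0.06883),
        ("Colombo", "LKA", 0.00009, 0.03605),
        ("Valencia", "ESP", 0.00009, 0.03335),
        ("Jeddah", "SAU", 0.00007, 0.02564),
        ("Barcelona", "ESP", 0.00005, 0.01947),
        ("Port Said", "EGY", 0.00004, 0.01504),
        ("Karachi", "PAK", 0.00004, 0.01407),
    ],
}
#: mean phi over all network locations used for per-pair relative rates
PAIR_MEAN_PHI = 0.00259

#: published arrivals-plus-departures counts for selected ports
DEGREE_CENTRALITY: dict[str, int] = {"Busan": 3086, "Kaohsiung": 2979, "Keelung": 758}
#: country-level degree centralities behind the corridor observation:
#: Yemen outranks Turkey and Pakistan on arrival rate despite under half
#: their degree centrality
COUNTRY_DEGREE_CENTRALITY: dict[str, int] = {"Yemen": 57, "Turkey": 113, "Pakistan": 125}

#: mean days at sea between consecutive ports of call
MEAN_LEG_DAYS = 7.9
#: published average span of a full ten-port call history: the nine legs
#: between ten ports at 7.9 days each, printed rounded to whole days
TEN_STEP_JOURNEY_DAYS = 71

#: scale of the original network extract
NETWORK_SCALE = {
    "foreign_ports": 553,
    "foreign_countries": 126,
    "domestic_ports": 30,
    "ships": 557,
    "call_events": 25507,
    "pest_countries": 36,
    "pest_countries_on_network": 24,
    "pest_origin_ports": 87,
    "simulations_per_origin": 2_000_000,
}


def korean_port_rates() -> dict[str, list[float]]:
    """Per-destination rates of each Korean origin port across all ten
    published destination panels, keyed by origin port."""
    rates: dict[str, list[float]] = {}
    for rows in PER_DESTINATION_TOP10.values():
        for port, country, phi, _rel in rows:
            if country == "KOR":
                rates.setdefault(port, []).append(phi)
    return rates
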