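"""Stoichiometry and thermodynamics of dissimilatory iodate respiration.

Growth on acetate with iodate as sole electron acceptor follows

    3 CH3COOH + 4 IO3-  ->  6 CO2 + 4 I- + 6 H2O

(8 electrons per acetate, 6 per iodate, 24 total), giving a theoretical
acceptor:donor ratio of 4/3.  The observed ratio falls short because part
of the consumed acetate is assimilated into biomass rather than respired;
the correction converts the optical-density increase to cell carbon
(0.39 g dry weight per litre per OD unit, ~50 % carbon) and compares the
iodate demand against the respired acetate only.

Energetics: dG per mole of electrons is -F (E_acceptor - E_donor) from
the redox-couple midpoint potentials.  The reductase itself transfers
only 4 electrons, producing hypoiodous acid (HIO), which abiotically
disproportionates 3 HIO -> 2 I- + IO3- + 3 H+; the regenerated iodate
re-enters the pathway, and the geometric series of recycling turns closes
the net 6-electron reduction of iodate to iodide.  The ledger simulates
that recycling explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FARADAY_KJ_PER_V_MOL = 96.485

THEORETICAL_RATIO = 4.0 / 3.0


@dataclass(frozen=True)
class GrowthMeasurement:
    """Consumption and growth deltas over one anaerobic growth experiment."""

    delta_acetate_mm: float
    delta_iodate_mm: float
    delta_od600: float

    def __post_init__(self) -> None:
        if min(self.delta_acetate_mm, self.delta_iodate_mm, self.delta_od600) < 0:
            raise ValueError("growth deltas must be nonnegative")


@dataclass(frozen=True)
class ConversionConstants:
    """Biomass and electron-accounting constants."""

    cdw_per_od: float = 0.39  # g dry weight / L per OD600 unit
    carbon_fraction_cdw: float = 0.50
    carbon_molar_mass: float = 12.011  # g/mol
    carbons_per_acetate: int = 2
    electrons_per_acetate: int = 8
    electrons_per_iodate: int = 6

    def __post_init__(self) -> None:
        for name in (
            "cdw_per_od",
            "carbon_fraction_cdw",
            "carbon_molar_mass",
            "carbons_per_acetate",
            "electrons_per_acetate",
            "electrons_per_iodate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RedoxCouple:
    name: str
    potential_v: float  # midpoint potential, volts
    electrons: int
    condition: str = "pH 7, 25 C"

    def __post_init__(self) -> None:
        if self.electrons < 1:
            raise ValueError("electrons must be >= 1")


# Reference couples.  Iodate/iodide is quoted at seawater pH; the acetate
# couple is the standard transformed value, exposed as a parameter because
# only the resulting dG is printed in most references.
IODATE_IODIDE = RedoxCouple("IO3-/I-", 0.72, 6, "pH 8.1, 25 C")
ACETATE_CO2 = RedoxCouple("CO2/acetate", -0.29, 8)
OXYGEN_WATER = RedoxCouple("O2/H2O", 0.820, 4)
NITRATE_N2 = RedoxCouple("NO3-/N2", 0.713, 5)
PERCHLORATE_CHLORIDE = RedoxCouple("ClO4-/Cl-", 0.797, 8)


@dataclass(frozen=True)
class StoichiometryResult:
    observed_ratio: float  # mol iodate / mol acetate consumed
    assimilated_acetate_mm: float
    assimilated_carbon_fraction: float
    respired_acetate_mm: float
    theoretical_ratio: float
    percent_of_theoretical: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.assimilated_carbon_fraction <= 1.0):
            raise ValueError("assimilated fraction must be in [0, 1]")


def observed_ratio(m: GrowthMeasurement) -> float:
    """Observed acceptor:donor ratio, mol iodate per mol acetate."""
    if m.delta_acetate_mm <= 0:
        raise ValueError("ratio undefined: no acetate consumed")
    return m.delta_iodate_mm / m.delta_acetate_mm


def assimilation_correction(
    m: GrowthMeasurement,
    c: ConversionConstants = ConversionConstants(),
) -> StoichiometryResult:
    """Biomass-corrected stoichiometry.

    The OD increase is converted to assimilated acetate
    (mM) via dry weight, carbon fraction, and carbons per acetate; the
    remainder of the consumed acetate is taken as respired, and the
    observed iodate demand is expressed as a percentage of the
    theoretical 4/3 ratio applied to the respired acetate.
    """
    if m.delta_acetate_mm <= 0:
        raise ValueError("no acetate consumed")
    assimilated = (
        m.delta_od600
        * c.cdw_per_od
        * c.carbon_fraction_cdw
        / c.carbon_molar_mass
        / c.carbons_per_acetate
        * 1000.0
    )  # mM acetate
    if assimilated >= m.delta_acetate_mm:
        raise ValueError(
            "inconsistent measurement: assimilated acetate exceeds consumption"
        )
    respired = m.delta_acetate_mm - assimilated
    percent = m.delta_iodate_mm / (respired * THEORETICAL_RATIO) * 100.0
    return StoichiometryResult(
        observed_ratio=observed_ratio(m),
        assimilated_acetate_mm=assimilated,
        assimilated_carbon_fraction=assimilated / m.delta_acetate_mm,
        respired_acetate_mm=respired,
        theoretical_ratio=THEORETICAL_RATIO,
        percent_of_theoretical=percent,
    )


@dataclass(frozen=True)
class BalanceReport:
    donor_coefficient: float
    acceptor_coefficient: float
    donor_electrons: float
    acceptor_electrons: float

    @property
    def balanced(self) -> bool:
        return abs(self.donor_electrons - self.acceptor_electrons) < 1e-9

    @property
    def imbalance(self) -> float:
        return self.donor_electrons - self.acceptor_electrons


def electron_balance(
    donor_coefficient: float = 3.0,
    acceptor_coefficient: float = 4.0,
    c: ConversionConstants = ConversionConstants(),
) -> BalanceReport:
    """Electron bookkeeping for a donor/acceptor coefficient pair.

    The printed respiration equation (3 acetate, 4 iodate) balances at
    24 electrons; other coefficients report their imbalance rather than
    raising.
    """
    return BalanceReport(
        donor_coefficient=donor_coefficient,
        acceptor_coefficient=acceptor_coefficient,
        donor_electrons=donor_coefficient * c.electrons_per_acetate,
        acceptor_electrons=acceptor_coefficient * c.electrons_per_iodate,
    )


def gibbs_per_electron(
    acceptor: RedoxCouple | float,
    donor: RedoxCouple | float,
    faraday: float = FARADAY_KJ_PER_V_MOL,
) -> float:
    """Gibbs free energy per mole of electrons, kJ/mol e-.

    dG/e- = -F (E_acceptor - E_donor); negative when the acceptor couple
    is more positive than the donor couple (energy-yielding respiration).
    """
    e_acc = acceptor.potential_v if isinstance(acceptor, RedoxCouple) else float(acceptor)
    e_don = donor.potential_v if isinstance(donor, RedoxCouple) else float(donor)
    return -faraday * (e_acc - e_don)


@dataclass
class DisproportionationLedger:
    """Bookkeeping of HIO recycling until the iodate pool is exhausted."""

    initial_iodate: float
    enzymatic_turnovers: float
    net_iodide: float
    electrons_transferred: float
    cycles_to_converge: int
    residual_iodate: float
    history: list[dict[str, float]] = field(default_factory=list)


def disproportionation_ledger(
    initial_iodate: float,
    tolerance: float = 1e-9,
    max_cycles: int = 10_000,
) -> DisproportionationLedger:
    """Simulate enzymatic 4-electron reduction plus abiotic recycling.

    Each cycle converts the entire current iodate pool to HIO (4 e- per
    molecule), then disproportionates the HIO into 2/3 iodide and 1/3
    iodate.  Iteration stops when the residual iodate falls below
    ``tolerance``.  Closed form (geometric series, sum (1/3)^k = 3/2):
    turnovers = 1.5 n0, electrons = 6 n0, iodide = n0 — the net
    6-electron reduction of iodate to iodide.
    """
    if initial_iodate < 0:
        raise ValueError("initial_iodate must be >= 0")
    iodate = float(initial_iodate)
    iodide = 0.0
    turnovers = 0.0
    cycles = 0
    history: list[dict[str, float]] = []
    while iodate >= tolerance and iodate > 0 and cycles < max_cycles:
        hio = iodate  # enzymatic step: IO3- + 4 e- -> HIO
        turnovers += iodate
        iodide += 2.0 / 3.0 * hio  # abiotic: 3 HIO -> 2 I- + IO3-
        iodate = hio / 3.0
        cycles += 1
        history.append(
            {"cycle": float(cycles), "iodate": iodate, "iodide": iodide, "turnovers": turnovers}
        )
    return DisproportionationLedger(
        initial_iodate=float(initial_iodate),
        enzymatic_turnovers=turnovers,
        net_iodide=iodide,
        electrons_transferred=4.0 * turnovers,
        cycles_to_converge=cycles,
        residual_iodate=iodate,
        history=history,
    )
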