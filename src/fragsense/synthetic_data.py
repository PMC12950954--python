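"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* the packaged fixture structures (the sensitiser fragment, the two
  reference panels, and the co-administered drugs) as a versioned SMILES
  file;
* toy fragment libraries mixing Rule-of-3-compliant and non-compliant
  molecules in a controlled proportion, assembled from scaffold and
  substituent template pools;
* plate-format viability matrices following a Hill inhibition model in which
  the sensitiser acts purely as a potency shift (no intrinsic toxicity),
  optionally with an additive hormesis bump at the top dose and Gaussian
  replicate noise.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from rdkit import Chem

from .chemstruct import Molecule, compute_descriptors, molecule_from_rdmol, parse_structure, ro3_filter
from .combination import DoseResponseMatrix

#: the dose grids of the co-administration experiment: seven drug-A
#: concentrations plus control, three sensitiser concentrations plus control
#: (all uM)
DEFAULT_DRUG_A_DOSES = (0.0, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0, 3.0)
DEFAULT_SENSITISER_DOSES = (0.0, 3.0, 10.0, 30.0)

#: printed Tc values of the two reference panels against the sensitiser
#: fragment, used as calibration data for the fingerprint scheme
PRINTED_TC_INHIBITORS = {
    "trigonelline": 0.61,
    "sc66": 0.55,
    "honokiol": 0.54,
    "loureirin_a": 0.53,
    "isc_4": 0.51,
}
PRINTED_TC_METABOLITES = {
    "tryptamine": 0.68,
    "n_methylserotonin": 0.67,
    "serotonin_1plus": 0.65,
    "metanephrine": 0.65,
    "indol_3_ylacetaldehyde": 0.65,
}


def fixture_structures() -> dict:
    """The packaged fixture set: name -> :class:`Molecule` (13 entries).

    Contains the sensitiser fragment (``bd_b10``), the five Akt-inhibitor
    references, the five natural-metabolite references, and the two
    co-administered drugs (gemcitabine, desipramine).
    """
    text = resources.files("fragsense.data").joinpath("fixtures.smi").read_text()
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, name = line.split("\t")
        out[name] = parse_structure(smiles, name)
    return out


def calibration_pairs() -> list:
    """The ten (fragment, reference, printed Tc) calibration triples."""
    fixtures = fixture_structures()
    query = fixtures["bd_b10"]
    pairs = []
    for table in (PRINTED_TC_INHIBITORS, PRINTED_TC_METABOLITES):
        for name, printed in table.items():
            pairs.append((query, fixtures[name], printed))
    return pairs


# ---------------------------------------------------------------------------
# fragment library generation
# ---------------------------------------------------------------------------

# small heterocyclic/carbocyclic scaffolds typical of Ro3 fragment libraries
_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccsc1", "c1ccoc1", "c1cc[nH]c1",
    "c1cnc[nH]1", "c1cc2ccccc2[nH]1", "c1csc(n1)C", "C1CCNCC1",
    "C1COCCN1", "c1cncnc1", "C1CCCCC1", "c1ccc2ccccc2c1", "C1CCNC1",
]

# small substituents; attached by a single bond to a scaffold atom
_SMALL_SUBS = ["C", "CC", "O", "N", "F", "Cl", "OC", "C#N", "C(C)=O", "CO", "C(N)=O"]

# heavy decorations used to breach the Rule of 3 (mass and/or lipophilicity)
_HEAVY_SUBS = [
    "CCCCCCCCCC", "CCCCCCCC", "c1ccc(-c2ccccc2)cc1", "C(F)(F)F",
    "CCCCCCc1ccccc1", "OCCCCCCCCCC",
]
# polar decorations used to breach the donor/acceptor/TPSA limits
_POLAR_SUBS = ["O", "N", "C(N)=O", "S(N)(=O)=O", "C(=O)O", "NC(N)=O"]


def _attach(core: Chem.Mol, sub: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Join a substituent to a random substitutable core atom by a single bond."""
    sites = [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() in (6, 7)
    ]
    if not sites:
        return None
    site = int(rng.choice(sites))
    combined = Chem.RWMol(Chem.CombineMols(core, sub))
    combined.AddBond(site, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combined.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _random_molecule(rng: np.random.Generator, compliant: bool) -> Chem.Mol | None:
    core = Chem.MolFromSmiles(str(rng.choice(_SCAFFOLDS)))
    if compliant:
        n_subs = int(rng.integers(0, 3))
        pools = [_SMALL_SUBS] * n_subs
    else:
        # breach by mass/lipophilicity or by polar-group overload
        if rng.random() < 0.6:
            pools = [_HEAVY_SUBS] + [_SMALL_SUBS] * int(rng.integers(0, 2)) + [_HEAVY_SUBS] * int(rng.integers(0, 2))
        else:
            pools = [_POLAR_SUBS] * int(rng.integers(4, 6))
    mol = core
    for pool in pools:
        sub = Chem.MolFromSmiles(str(rng.choice(pool)))
        mol = _attach(mol, sub, rng)
        if mol is None:
            return None
    return mol


def generate_fragment_library(
    n: int, frac_ro3: float = 0.5, seed: int = 0
) -> list[Molecule]:
    """Generate ``n`` fragments of which a Bernoulli(``frac_ro3``) share pass
    the Rule of 3 (each candidate is verified against ``ro3_filter`` and
    resampled until it lands in its assigned class).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= frac_ro3 <= 1.0:
        raise ValueError("frac_ro3 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    library = []
    for index in range(n):
        want_pass = bool(rng.random() < frac_ro3)
        for _attempt in range(200):
            rdmol = _random_molecule(rng, compliant=want_pass)
            if rdmol is None:
                continue
            mol = molecule_from_rdmol(rdmol, f"frag-{index:05d}")
            ok, _ = ro3_filter(compute_descriptors(mol))
            if ok == want_pass:
                library.append(mol)
                break
        else:  # pragma: no cover - template pools make this unreachable
            raise RuntimeError("could not realise the requested Ro3 class")
    return library


# ---------------------------------------------------------------------------
# dose-response simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillParams:
    """Ground-truth parameters of the simulated viability surface.

    The drug-alone curve is a Hill inhibition model
    ``v(g) = e0 - emax * g^h / (g^h + ec50^h)`` (viability %, dose uM).  The
    sensitiser shifts potency by the factor
    ``s(b) = 1 / (1 + rho * b / (b + kb))`` applied to ec50, so the implied
    dose-sparing at sensitiser dose ``b`` is ``1 - s(b)``.  ``hormesis_amp``
    adds a viability bump at the top drug-A dose; replicate noise is
    Gaussian with sd ``noise_sd`` (percentage points).

    Defaults emulate a 96-h gemcitabine exposure of a pancreatic carcinoma
    line: near-total potency in the 3-uM range is not reached (emax 85),
    mid-curve potency at 50 nM, and a moderately steep slope.
    """

    e0: float = 100.0
    emax: float = 85.0
    ec50: float = 0.05
    hill: float = 1.8
    rho: float = 0.117
    kb: float = 1.0
    hormesis_amp: float = 0.0
    noise_sd: float = 3.0
    n_reps: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")
        if not 0.0 <= self.emax <= 100.0:
            raise ValueError("emax must lie in [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def potency_factor(self, dose_b: float) -> float:
        return 1.0 / (1.0 + self.rho * dose_b / (dose_b + self.kb))

    def true_sparing(self, dose_b: float) -> float:
        """Dose-sparing fraction implied by the potency shift at ``dose_b``."""
        return 1.0 - self.potency_factor(dose_b)

    def mean_viability(self, dose_a: float, dose_b: float, top_dose: float) -> float:
        v = self.e0
        if dose_a > 0:
            shifted_ec50 = self.ec50 * self.potency_factor(dose_b)
            g_h = dose_a ** self.hill
            v -= self.emax * g_h / (g_h + shifted_ec50 ** self.hill)
        if dose_a == top_dose and dose_a > 0:
            v += self.hormesis_amp
        return v


def generate_dose_response(
    doses_a=DEFAULT_DRUG_A_DOSES,
    doses_b=DEFAULT_SENSITISER_DOSES,
    p: HillParams = HillParams(),
    cell_line: str = "synthetic",
) -> DoseResponseMatrix:
    """Simulate a replicate viability plate on the given dose grids."""
    rng = np.random.default_rng(p.seed)
    top = max(doses_a)
    signals = {}
    for a in doses_a:
        for b in doses_b:
            mean = p.mean_viability(a, b, top)
            signals[(float(a), float(b))] = mean + rng.normal(0.0, p.noise_sd, p.n_reps)
    return DoseResponseMatrix(
        drug_a_doses=tuple(float(a) for a in doses_a),
        sensitiser_doses=tuple(float(b) for b in doses_b),
        signals=signals,
        cell_line=cell_line,
    )


def with_seed(p: HillParams, seed: int) -> HillParams:
    """Copy of the parameters with a different RNG seed."""
    return replace(p, seed=seed)
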