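"""Energy backends: a uniform contract for optimization and single points.

Four backends share one interface (``optimize`` / ``single_point`` /
``species_energy``):

``surrogate``
    A deterministic closed-form potential used for all shipped tests and
    desk-scale runs.  The energy of a structure decomposes as

        E = sum_i element(i) + sum_bonds Morse(r_ij) + sum_nonbonded A e^{-r/rho}
            + state(moiety, charge) + sum_donors coupling(donor element)
            + motif bonus (if a ligand matches the configured SMARTS)

    with all parameters pinned in ``data/surrogate_params.json``.  Because the
    Morse term has a single minimum of depth -De per bond and the repulsion
    vanishes at separation, the surrogate is size-consistent and has a
    graph-computable analytic optimum (``analytic_energy``) that is used as a
    fast path when no 3D discrimination is required.

``xtb``
    Adapter around an external tight-binding program (GFN2-xTB / GFN-FF)
    exchanging XYZ files; raises :class:`BackendUnavailableError` when the
    executable is absent, which is distinct from a convergence failure.

``uff``
    RDKit UFF force-field pre-optimization (the cheap pre-screening level).

``dft_hook``
    Subclass hook for plugging in DFT; unavailable by default.

The connectivity check (``check_connectivity``) computes extended-Hückel
reduced overlap populations on a geometry and verifies every bond of the
reference graph against a threshold (default 0.15).
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdEHTTools

from .complex_model import Conformer, ValidationError

__all__ = [
    "EnergyResult",
    "BackendConfig",
    "BackendError",
    "BackendUnavailableError",
    "SurrogateBackend",
    "UFFBackend",
    "ExternalXTBBackend",
    "DFTHookBackend",
    "get_backend",
    "check_connectivity",
    "default_surrogate_params",
    "HARTREE_TO_KCAL",
]

HARTREE_TO_KCAL = 627.5094740631


class BackendError(RuntimeError):
    """Generic backend failure."""


class BackendUnavailableError(BackendError):
    """The backend's external executable or hook is missing in this environment."""


@dataclass
class EnergyResult:
    energy: float
    geometry: Conformer | None
    converged: bool
    backend_id: str


@dataclass
class BackendConfig:
    """Backend selection + opaque method options.

    ``options`` for the surrogate may carry ``params`` (a parameter dict
    overriding the pinned file), ``max_iterations`` and ``force_tol`` for the
    internal optimizer.
    """

    backend_id: str = "surrogate"
    options: dict = field(default_factory=dict)
    random_seed: int = 0


def default_surrogate_params() -> dict:
    return json.loads(
        resources.files("mofix.data").joinpath("surrogate_params.json").read_text()
    )


def _pair_key(e1: str, e2: str) -> str:
    return "-".join(sorted((e1, e2)))


class SurrogateBackend:
    """Deterministic surrogate potential with analytic optimum (see module docstring)."""

    backend_id = "surrogate"

    def __init__(self, params: Mapping | None = None):
        self.params = dict(params) if params is not None else default_surrogate_params()
        motif = self.params.get("motif") or {}
        smarts = motif.get("smarts")
        self._motif_query = Chem.MolFromSmarts(smarts) if smarts else None
        if smarts and self._motif_query is None:
            raise ValidationError(f"invalid motif SMARTS {smarts!r}")
        self._motif_bonus = float(motif.get("bonus", 0.0))
        self._motif_states = set(motif.get("states") or [])

    # -- parameter lookups ---------------------------------------------------

    def _element(self, symbol: str) -> float:
        try:
            return float(self.params["element_terms"][symbol])
        except KeyError:
            raise ValidationError(f"surrogate has no element term for {symbol!r}")

    def _pair(self, e1: str, e2: str) -> dict:
        return self.params["pair_terms"].get(_pair_key(e1, e2), self.params["pair_default"])

    # -- graph-level terms ----------------------------------------------------

    def _state_terms(self, mol: Chem.Mol) -> float:
        total = 0.0
        state_key = mol.GetProp("mofixStateKey") if mol.HasProp("mofixStateKey") else None
        if state_key is not None:
            total += float(self.params["state_terms"].get(state_key, 0.0))
            coupling = self.params.get("donor_coupling", {}).get(state_key)
            if coupling:
                for atom in mol.GetAtoms():
                    if atom.GetAtomicNum() != 42:
                        continue
                    for nb in atom.GetNeighbors():
                        if (
                            nb.HasProp("mofixRole")
                            and nb.GetProp("mofixRole") == "ligand"
                        ):
                            total += float(coupling.get(nb.GetSymbol(), 0.0))
            if (
                self._motif_query is not None
                and (not self._motif_states or state_key in self._motif_states)
                and mol.HasSubstructMatch(self._motif_query)
            ):
                total += self._motif_bonus
        if mol.HasProp("mofixStereoLabel"):
            stereo = self.params.get("stereo_terms", {})
            total += float(stereo.get(mol.GetProp("mofixStereoLabel"), 0.0))
        return total

    def _bonded_pairs(self, mol: Chem.Mol) -> list[tuple[int, int]]:
        return [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]

    # -- energies --------------------------------------------------------------

    def analytic_energy(self, mol: Chem.Mol) -> float:
        """Graph-level optimum: every bond at its Morse minimum, no strain.

        Hydrogens count whether explicit or implicit; implicit hydrogens
        contribute their element term and one X-H pair minimum each.
        """
        total = self._state_terms(mol)
        for atom in mol.GetAtoms():
            total += self._element(atom.GetSymbol())
            n_h = atom.GetTotalNumHs()
            if n_h:
                total += n_h * (self._element("H") - self._pair(atom.GetSymbol(), "H")["De"])
        for i, j in self._bonded_pairs(mol):
            e1 = mol.GetAtomWithIdx(i).GetSymbol()
            e2 = mol.GetAtomWithIdx(j).GetSymbol()
            total -= self._pair(e1, e2)["De"]
        return total

    def _compile(self, mol: Chem.Mol) -> dict:
        """Precompute pair index/parameter arrays for vectorized evaluation."""
        n = mol.GetNumAtoms()
        if n == 0:
            raise ValidationError("zero-atom input")
        symbols = [a.GetSymbol() for a in mol.GetAtoms()]
        const = self._state_terms(mol) + sum(self._element(s) for s in symbols)
        bonds = self._bonded_pairs(mol)
        bi = np.array([min(i, j) for i, j in bonds], dtype=int)
        bj = np.array([max(i, j) for i, j in bonds], dtype=int)
        de = np.array([self._pair(symbols[i], symbols[j])["De"] for i, j in bonds])
        r0 = np.array([self._pair(symbols[i], symbols[j])["r0"] for i, j in bonds])
        aa = np.array([self._pair(symbols[i], symbols[j])["a"] for i, j in bonds])
        iu, ju = np.triu_indices(n, k=1)
        bonded_flat = set(i * n + j for i, j in zip(bi, bj))
        nb_mask = np.array(
            [i * n + j not in bonded_flat for i, j in zip(iu, ju)], dtype=bool
        )
        return {
            "n": n,
            "const": const,
            "bi": bi,
            "bj": bj,
            "De": de,
            "r0": r0,
            "a": aa,
            "nbi": iu[nb_mask],
            "nbj": ju[nb_mask],
        }

    @staticmethod
    def _eval_compiled(data: dict, coords: np.ndarray, nb_params: dict) -> tuple[float, np.ndarray]:
        energy = data["const"]
        grad = np.zeros_like(coords)
        if len(data["bi"]):
            d = coords[data["bj"]] - coords[data["bi"]]
            r = np.maximum(np.linalg.norm(d, axis=1), 1e-8)
            u = d / r[:, None]
            ex = np.exp(-data["a"] * (r - data["r0"]))
            energy += float(np.sum(data["De"] * ((1.0 - ex) ** 2 - 1.0)))
            de_dr = 2.0 * data["De"] * data["a"] * (1.0 - ex) * ex
            f = de_dr[:, None] * u
            np.add.at(grad, data["bi"], -f)
            np.add.at(grad, data["bj"], f)
        if len(data["nbi"]):
            d = coords[data["nbj"]] - coords[data["nbi"]]
            r = np.maximum(np.linalg.norm(d, axis=1), 1e-8)
            u = d / r[:, None]
            rep = nb_params["A"] * np.exp(-r / nb_params["rho"])
            energy += float(np.sum(rep))
            de_dr = -rep / nb_params["rho"]
            f = de_dr[:, None] * u
            np.add.at(grad, data["nbi"], -f)
            np.add.at(grad, data["nbj"], f)
        return energy, grad

    def _eval(self, mol: Chem.Mol, coords: np.ndarray) -> tuple[float, np.ndarray]:
        data = self._compile(mol)
        return self._eval_compiled(data, np.asarray(coords, dtype=float), self.params["nonbonded"])

    # -- backend contract -------------------------------------------------------

    def single_point(self, conformer: Conformer, **_: object) -> EnergyResult:
        energy, _grad = self._eval(conformer.mol, conformer.coords)
        geom = conformer.with_coords(conformer.coords, energy=energy)
        return EnergyResult(energy, geom, True, self.backend_id)

    def optimize(
        self,
        conformer: Conformer,
        max_iterations: int = 5000,
        force_tol: float = 0.1,
        frozen: Sequence[int] | None = None,
        **_: object,
    ) -> EnergyResult:
        """L-BFGS-B minimization with the analytic surrogate gradient.

        Monotone line searches guarantee the returned energy never exceeds
        the input single-point energy.  ``frozen`` atoms are held fixed via
        equal bounds.  Convergence means the free-atom gradient norm is below
        ``force_tol`` (kcal/mol/A) within ``max_iterations`` iterations.
        """
        from scipy.optimize import minimize

        x0 = conformer.coords.reshape(-1)
        n = len(conformer.coords)
        mask = np.ones(n, dtype=bool)
        if frozen is not None:
            mask[list(frozen)] = False
        data = self._compile(conformer.mol)
        nb_params = self.params["nonbonded"]

        def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
            e, g = self._eval_compiled(data, x.reshape(n, 3), nb_params)
            g = np.where(mask[:, None], g, 0.0)
            return e, g.reshape(-1)

        bounds = None
        if frozen is not None:
            bounds = [
                (v, v) if not mask[i // 3] else (None, None)
                for i, v in enumerate(x0)
            ]
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": int(max_iterations),
                "gtol": force_tol / 10.0,
                "ftol": 1e-13,
            },
        )
        coords = res.x.reshape(n, 3)
        energy, grad = self._eval(conformer.mol, coords)
        g = np.where(mask[:, None], grad, 0.0)
        converged = bool(np.abs(g).max() <= force_tol) if g.size else True
        geom = conformer.with_coords(coords, energy=energy)
        return EnergyResult(energy, geom, converged, self.backend_id)

    def species_energy(self, name: str) -> float:
        try:
            return float(self.params["species_energies"][name])
        except KeyError:
            raise ValidationError(f"no pinned species energy for {name!r}")


class UFFBackend:
    """RDKit UFF force field; the cheap pre-optimization level."""

    backend_id = "uff"

    def optimize(self, conformer: Conformer, max_iterations: int = 200, **_: object) -> EnergyResult:
        mol = Chem.Mol(conformer.mol)
        try:
            ff = AllChem.UFFGetMoleculeForceField(mol)
            if ff is None:
                raise BackendError("UFF setup failed")
            status = ff.Minimize(maxIts=int(max_iterations))
            energy = ff.CalcEnergy()
        except Exception as exc:  # noqa: BLE001 - UFF failure = non-convergence
            return EnergyResult(float("nan"), conformer, False, self.backend_id)
        geom = Conformer(mol, conformer.total_charge, conformer.multiplicity, energy)
        return EnergyResult(energy, geom, status == 0, self.backend_id)

    def single_point(self, conformer: Conformer, **_: object) -> EnergyResult:
        mol = Chem.Mol(conformer.mol)
        try:
            ff = AllChem.UFFGetMoleculeForceField(mol)
            if ff is None:
                raise BackendError("UFF setup failed")
            energy = ff.CalcEnergy()
        except Exception:  # noqa: BLE001
            return EnergyResult(float("nan"), conformer, False, self.backend_id)
        return EnergyResult(energy, conformer, True, self.backend_id)

    def species_energy(self, name: str) -> float:
        raise BackendUnavailableError("UFF backend has no donor species energies")


class ExternalXTBBackend:
    """Adapter for an external ``xtb`` executable (GFN2-xTB or GFN-FF).

    Exchanges XYZ files, passes charge and multiplicity via ``--chrg`` and
    ``--uhf`` and parses the total-energy line.  Every invocation is logged to
    ``self.call_log`` for provenance.
    """

    def __init__(self, executable: str = "xtb", method: str = "gfn2"):
        self.executable = executable
        self.method = method
        self.backend_id = f"xtb-{method}"
        self.call_log: list[list[str]] = []

    def _require(self) -> str:
        path = shutil.which(self.executable)
        if path is None:
            raise BackendUnavailableError(
                f"external executable {self.executable!r} not found on PATH"
            )
        return path

    def _run(self, conformer: Conformer, extra: list[str]) -> EnergyResult:
        from .io import write_xyz, read_xyz  # local import to avoid cycle

        exe = self._require()
        with tempfile.TemporaryDirectory() as tmp:
            xyz = Path(tmp) / "input.xyz"
            write_xyz(xyz, conformer)
            method_flag = "--gfnff" if self.method == "gfnff" else "--gfn"
            cmd = [exe, str(xyz), "--chrg", str(conformer.total_charge),
                   "--uhf", str(conformer.multiplicity - 1)]
            if self.method == "gfnff":
                cmd.append("--gfnff")
            else:
                cmd += ["--gfn", "2"]
            cmd += extra
            self.call_log.append(cmd)
            proc = subprocess.run(
                cmd, cwd=tmp, capture_output=True, text=True, check=False
            )
            energy = None
            for line in proc.stdout.splitlines():
                if "TOTAL ENERGY" in line:
                    energy = float(line.split()[-3]) * HARTREE_TO_KCAL
            if energy is None:
                return EnergyResult(float("nan"), conformer, False, self.backend_id)
            geom = conformer
            opt_path = Path(tmp) / "xtbopt.xyz"
            if opt_path.exists():
                geom = conformer.with_coords(read_xyz(opt_path)[1], energy=energy)
            return EnergyResult(energy, geom, proc.returncode == 0, self.backend_id)

    def optimize(self, conformer: Conformer, **_: object) -> EnergyResult:
        return self._run(conformer, ["--opt"])

    def single_point(self, conformer: Conformer, **_: object) -> EnergyResult:
        return self._run(conformer, [])

    def species_energy(self, name: str) -> float:
        raise BackendUnavailableError(
            "donor species energies must be computed from bundled geometries"
        )


class DFTHookBackend:
    """Placeholder contract for plugging in a DFT engine; unavailable by default."""

    backend_id = "dft_hook"

    def optimize(self, conformer: Conformer, **_: object) -> EnergyResult:
        raise BackendUnavailableError("no DFT engine configured")

    def single_point(self, conformer: Conformer, **_: object) -> EnergyResult:
        raise BackendUnavailableError("no DFT engine configured")

    def species_energy(self, name: str) -> float:
        raise BackendUnavailableError("no DFT engine configured")


def get_backend(config: BackendConfig):
    if config.backend_id == "surrogate":
        return SurrogateBackend(config.options.get("params"))
    if config.backend_id in ("xtb", "tight_binding"):
        return ExternalXTBBackend(
            config.options.get("executable", "xtb"),
            config.options.get("method", "gfn2"),
        )
    if config.backend_id in ("uff", "ff_preopt"):
        return UFFBackend()
    if config.backend_id == "dft_hook":
        return DFTHookBackend()
    raise ValidationError(f"unknown backend {config.backend_id!r}")


# --------------------------------------------------------------------------- #
# Extended-Hückel connectivity check
# --------------------------------------------------------------------------- #


def _rop_lookup(rop: np.ndarray, i: int, j: int) -> float:
    a, b = max(i, j), min(i, j)
    return float(rop[a * (a + 1) // 2 + b])


def check_connectivity(
    conformer: Conformer,
    reference_mol: Chem.Mol | None = None,
    threshold: float = 0.15,
) -> bool:
    """True iff every bond of the reference graph has an extended-Hückel
    reduced overlap population >= ``threshold`` at the conformer's geometry.

    A bond that has effectively broken during optimization has vanishing
    overlap population, so this catches ligand dissociation and moiety
    rearrangement.  ``threshold=0`` accepts any finite geometry.
    """
    ref = reference_mol if reference_mol is not None else conformer.mol
    if ref.GetNumAtoms() != conformer.n_atoms:
        raise ValidationError("geometry does not match reference graph")
    if conformer.n_atoms == 0:
        raise ValidationError("zero-atom input")
    if threshold <= 0:
        return True
    try:
        ok, result = rdEHTTools.RunMol(conformer.mol)
    except Exception as exc:  # noqa: BLE001
        raise BackendError(f"extended-Hückel run failed: {exc}") from exc
    if not ok:
        raise BackendError("extended-Hückel run did not converge")
    rop = np.asarray(result.GetReducedOverlapPopulationMatrix())
    for bond in ref.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if _rop_lookup(rop, i, j) < threshold:
            return False
    return True
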