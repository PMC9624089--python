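import numpy as np
import pytest

import plastiqtl as pq


@pytest.fixture(scope="session")
def small_panel():
    """100 lines × 400 markers on 4 chromosomes, weak blockwise LD."""
    cfg = pq.PanelConfig(n_lines=100, n_markers=400, n_chromosomes=4, seed=11)
    return pq.simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def qc_panel(small_panel):
    G, mmap = small_panel
    Gf, _ = pq.filter_markers(G)
    Gi = pq.impute_missing(Gf)
    K = pq.vanraden_kinship(Gi)
    return Gi, mmap.subset(Gi.marker_ids), K


@pytest.fixture(scope="session")
def sim_study(qc_panel):
    """Phenotypes with one main-effect and one interacting QTL injected."""
    G, mmap, K = qc_panel
    p = pq.allele_frequencies(G)
    maf = np.minimum(p, 1 - p)
    common = np.flatnonzero(maf >= 0.3)
    qtls = (
        pq.QtlEffect(str(G.marker_ids[common[0]]), 22.0, 0.0),
        pq.QtlEffect(str(G.marker_ids[common[-1]]), 8.0, 12.0),
    )
    pheno, truth = pq.simulate_phenotypes(G, K, pq.TraitConfig(qtl_list=qtls), seed=13)
    return pheno, truth


@pytest.fixture(scope="session")
def height_fit(sim_study):
    pheno, _ = sim_study
    return pq.fit_height_model(pheno)


@pytest.fixture(scope="session")
def study_blues(height_fit):
    return pq.extract_blues(height_fit)
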