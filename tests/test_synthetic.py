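import numpy as np
import pytest

from scenebound import (
    StudyConfig,
    generate_descriptions,
    generate_embeddings,
    generate_image,
    generate_study,
)
from scenebound.behavior import score_table
from scenebound.semantic import lexical_entropy, mean_pairwise_distance
from scenebound.synthetic import InvalidParameterError, lab_palette
from scenebound.visual import (
    color_histogram,
    compute_color_entropy,
    compute_edge_density,
)


class TestImages:
    def test_blank_canvas_has_no_edges_and_no_color_variety(self):
        img = generate_image(n_shapes=0, palette_size=1, seed=0)
        assert compute_edge_density(img) == 0
        assert compute_color_entropy(img) == 0.0

    def test_four_equal_stripes_give_two_bits(self):
        img = generate_image(n_shapes=0, palette_size=4, size=360, seed=0)
        assert compute_color_entropy(img) == pytest.approx(2.0, abs=1e-9)

    def test_palette_occupies_distinct_bins(self):
        for k in (2, 6, 12, 16):
            img = generate_image(n_shapes=0, palette_size=k, size=352, seed=0)
            occupied = int((color_histogram(img) > 0).sum())
            assert occupied == k

    def test_seeded_determinism(self):
        a = generate_image(n_shapes=8, palette_size=5, seed=42)
        b = generate_image(n_shapes=8, palette_size=5, seed=42)
        assert np.array_equal(a.pixels, b.pixels)

    def test_more_shapes_mean_more_edges(self):
        few = generate_image(n_shapes=3, palette_size=4, seed=1)
        many = generate_image(n_shapes=25, palette_size=4, seed=1)
        assert compute_edge_density(many) > compute_edge_density(few)

    def test_more_palette_colors_mean_more_color_entropy(self):
        low = generate_image(n_shapes=0, palette_size=2, seed=2)
        high = generate_image(n_shapes=0, palette_size=10, seed=2)
        assert compute_color_entropy(high) > compute_color_entropy(low)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_image(n_shapes=-1, palette_size=2)
        with pytest.raises(InvalidParameterError):
            generate_image(n_shapes=2, palette_size=0)
        with pytest.raises(InvalidParameterError):
            lab_palette(500)


class TestDescriptions:
    def test_single_content_word_has_zero_lexical_entropy(self):
        descs = generate_descriptions(target_length=8, vocab_size=1, seed=0)
        assert lexical_entropy(descs) == 0.0

    def test_doubling_target_length_doubles_median(self):
        from scenebound.semantic import description_length

        short = generate_descriptions(target_length=8, vocab_size=50, seed=1)
        long = generate_descriptions(target_length=16, vocab_size=50, seed=1)
        m_short = np.median([description_length(d) for d in short])
        m_long = np.median([description_length(d) for d in long])
        assert m_long == pytest.approx(2 * m_short, rel=0.25)

    def test_larger_vocabulary_raises_lexical_entropy(self):
        small = generate_descriptions(target_length=10, vocab_size=5, seed=2)
        large = generate_descriptions(target_length=10, vocab_size=80, seed=2)
        assert lexical_entropy(large) > lexical_entropy(small)

    def test_flatter_zipf_raises_lexical_entropy(self):
        steep = generate_descriptions(10, 50, zipf_exponent=2.0, seed=3)
        flat = generate_descriptions(10, 50, zipf_exponent=0.5, seed=3)
        assert lexical_entropy(flat) > lexical_entropy(steep)

    def test_seeded_determinism(self):
        assert generate_descriptions(10, 30, seed=9) == generate_descriptions(
            10, 30, seed=9
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_descriptions(target_length=0, vocab_size=5)
        with pytest.raises(InvalidParameterError):
            generate_descriptions(target_length=5, vocab_size=0)


class TestEmbeddings:
    def test_single_cluster_zero_spread_collapses_distances(self):
        vocab = [f"word{i}" for i in range(10)]
        emb = generate_embeddings(vocab, n_clusters=1, spread=0.0, seed=0)
        assert mean_pairwise_distance([" ".join(vocab)], emb) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_orthogonal_centroids_give_unit_cross_distance(self):
        emb = generate_embeddings(["c00w000", "c01w000"], n_clusters=2, spread=0.0,
                                  seed=0)
        v0, v1 = emb.vector("c00w000"), emb.vector("c01w000")
        assert v0 @ v1 == pytest.approx(0.0, abs=1e-12)
        assert mean_pairwise_distance(["c00w000 c01w000"], emb) == pytest.approx(1.0)

    def test_vectors_are_unit_norm(self):
        emb = generate_embeddings([f"w{i}" for i in range(6)], dim=10, n_clusters=3,
                                  spread=0.4, seed=1)
        for w in emb.vocabulary:
            assert np.linalg.norm(emb.vector(w)) == pytest.approx(1.0)

    def test_more_clusters_raise_mean_pairwise_distance(self):
        vocab = [f"word{i}" for i in range(24)]
        text = " ".join(vocab)
        vals = []
        for k in (1, 3, 8):
            emb = generate_embeddings(vocab, n_clusters=k, spread=0.05, seed=2)
            vals.append(mean_pairwise_distance([text], emb))
        assert vals[0] < vals[1] < vals[2]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_embeddings(["a"], dim=1)
        with pytest.raises(InvalidParameterError):
            generate_embeddings(["a"], dim=5, n_clusters=9)


class TestStudy:
    def test_pure_intercept_model_saturates_extension(self):
        cfg = StudyConfig(
            n_images=10, n_participants=12,
            beta=(1.0, 0.0, 0.0, 0.0), noise_sd=0.0, seed=0,
        )
        study = generate_study(cfg, with_features=False)
        assert np.all(study.true_scores == 1.0)
        assert (study.responses["response"] == "closer").all()
        scores = score_table(study.responses)
        assert (scores["score"] == 1.0).all()

    def test_mean_score_converges_to_true_score(self):
        cfg = StudyConfig(n_images=10, n_participants=2000, seed=1)
        study = generate_study(cfg, with_features=False)
        scores = score_table(study.responses).set_index("image_id")
        for i, iid in enumerate(study.image_ids):
            s = study.true_scores[i]
            se = np.sqrt(max(1e-12, 1 - s**2) / cfg.n_participants)
            assert abs(scores.loc[iid, "score"] - s) <= max(3 * se, 3 / cfg.n_participants)

    def test_score_variance_matches_binomial_model(self):
        # Var[score_i] = (1 - s_i^2) / n under the (1+s)/2 response model.
        # With b0 = 0.3 and all other terms zero, every image of every
        # study has true score 0.3, so scores pooled over seeds form an
        # iid sample whose moments the model pins down.
        s, n_part = 0.3, 50
        scores = []
        for seed in range(40):
            cfg = StudyConfig(
                n_images=10, n_participants=n_part,
                beta=(s, 0.0, 0.0, 0.0), noise_sd=0.0, seed=seed,
            )
            study = generate_study(cfg, with_features=False)
            scores.extend(score_table(study.responses)["score"].tolist())
        scores = np.asarray(scores)  # 400 iid draws
        expected_var = (1 - s**2) / n_part
        assert scores.mean() == pytest.approx(s, abs=4 * np.sqrt(expected_var / 400))
        assert np.var(scores, ddof=1) == pytest.approx(expected_var, rel=0.25)

    def test_seeded_determinism_and_complete_responses(self):
        cfg = StudyConfig(n_images=12, n_participants=15, seed=5)
        a = generate_study(cfg, with_features=False)
        b = generate_study(cfg, with_features=False)
        assert a.responses.equals(b.responses)
        assert np.array_equal(a.true_scores, b.true_scores)
        assert len(a.responses) == 12 * 15  # every participant x image pair

    def test_generated_tables_pass_consumers_cleanly(self):
        import warnings

        from scenebound.semantic import semantic_feature_table
        from scenebound.visual import visual_feature_table

        cfg = StudyConfig(n_images=10, n_participants=10, seed=7)
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # any validator warning fails
            study = generate_study(cfg)
            vis = visual_feature_table(study.images)
            sem = semantic_feature_table(study.corpora, study.embeddings)
        assert len(vis) == len(sem) == 10
        assert np.all(np.abs(study.true_scores) <= 1.0)
        assert set(vis["image_id"]) == set(sem["image_id"]) == set(study.image_ids)

    def test_latents_steer_measured_features(self):
        cfg = StudyConfig(n_images=30, n_participants=10, seed=8)
        study = generate_study(cfg)
        from scenebound.semantic import semantic_feature_table
        from scenebound.unify import unify_features
        from scenebound.visual import visual_feature_table

        sem_scores, _ = unify_features(
            semantic_feature_table(study.corpora, study.embeddings), "semantic"
        )
        vis_scores, _ = unify_features(visual_feature_table(study.images), "visual")
        r_sem = np.corrcoef(study.latent_semantic, sem_scores["semantic_info"])[0, 1]
        r_vis = np.corrcoef(study.latent_visual, vis_scores["visual_info"])[0, 1]
        assert r_sem > 0.8
        assert r_vis > 0.7

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidParameterError):
            StudyConfig(n_images=5)
        with pytest.raises(InvalidParameterError):
            StudyConfig(depth_range=(3.0, 1.0))
        with pytest.raises(InvalidParameterError):
            StudyConfig(noise_sd=-0.1)
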