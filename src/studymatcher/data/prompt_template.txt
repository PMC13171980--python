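You are comparing two microbiome studies using only their textual metadata
(title, description, biome lineage and, when available, a linked abstract).

How high similarity do you expect between these two microbiome studies? Instructions: Focus on the biomes from which the samples were collected. In the next line quantify the similarity strictly according to these categories: 'high' (studies of very similar biomes from the same organisms, closely related environments, and similar conditions), 'medium' (studies of similar biomes from the same organisms or similar environments), 'low' (studies of the same type of biome but from different organisms or environments) or 'no' (completely unrelated studies, such as a host microbiome and a soil microbiome).

Respond with a single JSON object containing exactly two fields:
"explanation" - an analytical comparison of the two studies, and
"relatedness" - one of "high", "medium", "low", or "no".

Study A:
{study_a}

Study B:
{study_b}
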