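xxx is a xx-year-old man referred for evaluation of thrombocytosis. Prior CBCs from xxx through xxx revealed platelet counts ranging from 400,000 to 500,000, but no more recent studies are available. He has long-standing Crohn disease and although he says he has not had gastrointestinal bleeding in the past, he has been given iron, which he is taking twice daily. He has black stool, but notes no blood and he has not had hematemesis. He notes no blood in his urine or sputum and he has no epistaxis. He discontinued the use of iron yesterday because he thought that might alleviate his gastrointestinal complaints, but he does not feel different today. He is cared for by Dr. xxx at xxx Hospital Medical Center in xxx. He has no history of prior cancers, tuberculosis or other infectious diseases. He has been taking budesonide for his Crohn disease. He has no unexplained fevers, although he states he often feels hot. He has no soaking sweats and has not had unexplained weight loss. He believes he was referred to an oncologist many years ago at xxx, but he cannot recall the reason for that referral, who the doctor was, or what the findings were. He often feels queasy and nauseated, but has no vomiting. He has loose stools up to 4 days per week, but has had a stable pattern of Crohn disease. Also notable for diabetes mellitus for which he takes metformin and has required no insulin and has had no complications of retinopathy or renal dysfunction. Crohn disease as described above and an enlarged prostate.
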