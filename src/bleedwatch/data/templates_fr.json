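{
  "language": "fr",
  "filler": [
    "Le patient est resté stable sous régime habituel.",
    "Les constantes vitales sont restées dans la norme.",
    "Séance de physiothérapie effectuée sans incident.",
    "Bilan rénal sans particularité ce matin.",
    "Mobilisation dans le couloir avec aide.",
    "Projet de sortie discuté avec la famille.",
    "Tension artérielle contrôlée sous traitement actuel."
  ],
  "negation": [
    "Pas de saignement observé durant le séjour.",
    "Aucune hémorragie constatée à l'examen.",
    "Pas de sang dans les selles.",
    "Aucun signe de saignement au point de ponction."
  ],
  "active_mb": [
    "Hémorragie massive avec choc hémodynamique nécessitant une réanimation urgente.",
    "Saignement digestif majeur avec transfusion en urgence.",
    "Hémorragie intracrânienne sévère confirmée à l'imagerie.",
    "Hématémèse profuse avec hypotension et protocole transfusionnel massif.",
    "Hémorragie rétropéritonéale menaçante avec effondrement de l'hémoglobine."
  ],
  "active_crnmb": [
    "Épistaxis légère contrôlée par compression locale.",
    "Saignement mineur des gencives constaté la nuit.",
    "Petit hématome sous-cutané au site d'injection.",
    "Hématurie modérée sans retentissement hémodynamique.",
    "Rectorragie limitée résolutive spontanément."
  ],
  "antecedent": [
    "Antécédent de saignement un an avant l'admission.",
    "Hémorragie antérieure documentée lors du séjour précédent.",
    "Méléna ancien rapporté il y a plusieurs mois.",
    "Ancien ulcère hémorragique traité par endoscopie par le passé."
  ]
}
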