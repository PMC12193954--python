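# Synthetic token -> cluster-id fixture table.
# Stand-in for a large Twitter-derived hierarchical word clustering; groups
# lexical variants and near-synonyms from the template vocabulary into
# shared cluster ids. Two columns: token <TAB> cluster id.
tremor	c_motor
tremors	c_motor
trembling	c_motor
shaking	c_motor
shaky	c_motor
shakes	c_motor
twitch	c_motor
twitching	c_motor
spasm	c_motor
spasms	c_motor
stiff	c_rigid
stiffness	c_rigid
rigid	c_rigid
rigidity	c_rigid
cramp	c_rigid
cramps	c_rigid
slow	c_slow
slowness	c_slow
bradykinesia	c_slow
freezing	c_slow
frozen	c_slow
shuffling	c_gait
shuffle	c_gait
stooped	c_gait
hunched	c_gait
balance	c_gait
imbalance	c_gait
unsteady	c_gait
fall	c_fall
falls	c_fall
fell	c_fall
falling	c_fall
fallen	c_fall
stumbled	c_fall
tripped	c_fall
dizzy	c_fall
dizziness	c_fall
fatigue	c_tired
fatigued	c_tired
tired	c_tired
exhausted	c_tired
exhaustion	c_tired
sleep	c_sleep
sleepless	c_sleep
insomnia	c_sleep
nightmares	c_sleep
dreams	c_sleep
pain	c_pain
aching	c_pain
aches	c_pain
sore	c_pain
numbness	c_pain
tingling	c_pain
anxiety	c_mood
anxious	c_mood
depression	c_mood
depressed	c_mood
apathy	c_mood
memory	c_cognitive
forgetful	c_cognitive
confusion	c_cognitive
hallucinations	c_cognitive
levodopa	c_drug
carbidopa	c_drug
sinemet	c_drug
rytary	c_drug
rasagiline	c_drug
azilect	c_drug
amantadine	c_drug
pramipexole	c_drug
mirapex	c_drug
ropinirole	c_drug
requip	c_drug
rotigotine	c_drug
neupro	c_drug
dopamine	c_drug
meds	c_drug
medication	c_drug
dose	c_drug
dosage	c_drug
prescription	c_drug
pills	c_drug
doctor	c_clinic
neurologist	c_clinic
specialist	c_clinic
hospital	c_clinic
clinic	c_clinic
appointment	c_clinic
checkup	c_clinic
nurse	c_clinic
surgery	c_clinic
therapy	c_clinic
therapist	c_clinic
diagnosis	c_clinic
diagnosed	c_clinic
symptoms	c_clinic
disease	c_clinic
parkinson	c_pd
parkinsons	c_pd
parkinsonism	c_pd
pd	c_pd
dbs	c_pd
exercise	c_fitness
exercising	c_fitness
workout	c_fitness
gym	c_fitness
boxing	c_fitness
yoga	c_fitness
treadmill	c_fitness
cycling	c_fitness
pedaling	c_fitness
stretching	c_fitness
pilates	c_fitness
zumba	c_fitness
marathon	c_fitness
5k	c_fitness
hike	c_fitness
hiking	c_fitness
walk	c_fitness
walking	c_fitness
foundation	c_advocacy
fundraiser	c_advocacy
donate	c_advocacy
awareness	c_advocacy
support	c_advocacy
volunteer	c_advocacy
charity	c_advocacy
research	c_advocacy
trial	c_advocacy
study	c_advocacy
love	c_social
wedding	c_social
birthday	c_social
party	c_social
family	c_social
grandkids	c_social
granddaughter	c_social
grandson	c_social
niece	c_social
nephew	c_social
friends	c_social
dinner	c_food
recipe	c_food
coffee	c_food
cake	c_food
pie	c_food
roast	c_food
barbecue	c_food
game	c_leisure
beach	c_leisure
lake	c_leisure
garden	c_leisure
vacation	c_leisure
concert	c_leisure
movie	c_leisure
trivia	c_leisure
volleyball	c_leisure
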